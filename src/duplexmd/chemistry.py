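"""Per-residue atom-role tables shared by the contact and base-pair analyses.

The base moiety of a nucleotide is its ring heavy atoms plus exocyclic N/O
substituents — no sugar, no phosphate.  A protein "side chain" is every
heavy atom past CB (CB included); for glycine the CA stands in.  Charged
groups are the terminal side-chain moieties (guanidinium nitrogens for Arg,
NZ for Lys).
"""

from __future__ import annotations

import numpy as np

from .structure_io import Topology, normalize_base

#: Heavy atoms forming the base moiety (purine and pyrimidine names pooled;
#: primes keep sugar atoms like C5' out of this set).
BASE_ATOM_NAMES = frozenset({
    "N1", "C2", "N3", "C4", "C5", "C6",        # shared ring
    "N7", "C8", "N9",                          # purine second ring
    "N6", "O6", "N2",                          # purine exocyclic
    "O2", "N4", "O4", "C7",                    # pyrimidine exocyclic (+thymine methyl)
})

PROTEIN_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})

HYDROPHOBIC_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"})
CHARGED_RESIDUES = frozenset({"ARG", "LYS"})

#: Side-chain charged-group heavy atoms of the positively charged residues.
CHARGED_GROUP_ATOMS = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

#: Side-chain hydrogen-bond donor / acceptor heavy atoms per protein residue.
PROTEIN_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "TRP": {"NE1"}, "CYS": {"SG"},
}
PROTEIN_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"},
}

#: Base hydrogen-bond donors/acceptors by one-letter base identity.
BASE_DONORS = {"A": {"N6"}, "G": {"N1", "N2"}, "C": {"N4"}, "U": {"N3"}}
BASE_ACCEPTORS = {"A": {"N1", "N3", "N7"}, "G": {"O6", "N3", "N7"},
                  "C": {"O2", "N3"}, "U": {"O2", "O4"}}

#: RNA backbone/sugar acceptors (both phosphate oxygen naming dialects).
RNA_BACKBONE_ACCEPTORS = frozenset({"OP1", "OP2", "O1P", "O2P",
                                    "O2'", "O3'", "O4'", "O5'"})
RNA_BACKBONE_DONORS = frozenset({"O2'"})


def _heavy(topo: Topology, idx: np.ndarray) -> np.ndarray:
    return idx[topo.elements[idx] != "H"]


def base_atom_indices(topo: Topology, res_idx: np.ndarray) -> np.ndarray:
    """Heavy base-moiety atoms of a nucleotide (given its atom indices)."""
    mask = np.isin(topo.names[res_idx], sorted(BASE_ATOM_NAMES))
    return _heavy(topo, res_idx[mask])


def sidechain_atom_indices(topo: Topology, res_idx: np.ndarray) -> np.ndarray:
    """Heavy side-chain atoms of a protein residue; CA for glycine."""
    names = topo.names[res_idx]
    mask = ~np.isin(names, sorted(PROTEIN_BACKBONE))
    sc = _heavy(topo, res_idx[mask])
    if sc.size == 0:  # glycine (or stripped side chain)
        sc = res_idx[names == "CA"]
    return sc


def charged_group_indices(topo: Topology, res_idx: np.ndarray, resname: str) -> np.ndarray:
    group = CHARGED_GROUP_ATOMS.get(resname)
    if group is None:
        return np.array([], dtype=int)
    mask = np.isin(topo.names[res_idx], sorted(group))
    return res_idx[mask]


def donor_acceptor_indices(topo: Topology, res_idx: np.ndarray,
                           resname: str) -> tuple[np.ndarray, np.ndarray]:
    """(donor, acceptor) heavy-atom indices of a residue or nucleotide."""
    names = topo.names[res_idx]
    base = normalize_base(resname)
    if base is not None:
        donors = set(BASE_DONORS[base]) | set(RNA_BACKBONE_DONORS)
        acceptors = set(BASE_ACCEPTORS[base]) | set(RNA_BACKBONE_ACCEPTORS)
    else:
        donors = set(PROTEIN_SIDECHAIN_DONORS.get(resname, set()))
        acceptors = set(PROTEIN_SIDECHAIN_ACCEPTORS.get(resname, set()))
        if resname != "PRO":
            donors.add("N")        # backbone amide
        acceptors.update({"O", "OXT"})  # backbone carbonyl
    d = res_idx[np.isin(names, sorted(donors))]
    a = res_idx[np.isin(names, sorted(acceptors))]
    return _heavy(topo, d), _heavy(topo, a)
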