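"""Three-class residue-nucleotide interaction census with trajectory occupancy.

Three geometric contact classes are inventoried between every protein
residue and every nucleotide, frame by frame:

* hydrophobic — side-chain center of mass within 6.5 Å of the base center
  of mass (hydrophobic residue set only);
* electrostatic — charged-group center of mass (Arg guanidinium nitrogens,
  Lys NZ) within 11 Å of the nucleotide's backbone phosphorus;
* hydrogen bond — any donor/acceptor heavy-atom pair within 3.5 Å, plus a
  D-H...A angle criterion when hydrogens are present in the topology.

The occupancy ("population") of a contact is the fraction of frames in
which its criterion holds; the census is typically filtered to contacts
present in strictly more than half the frames.  Distance comparisons at the
cutoffs are strict (<) for the COM classes and inclusive (<=) for the
donor-acceptor distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chemistry
from .structure_io import Topology, Trajectory, normalize_base

__all__ = [
    "ContactConfig",
    "ContactSummary",
    "hydrophobic_contacts",
    "electrostatic_contacts",
    "hydrogen_bonds",
    "filter_by_population",
    "compare_censuses",
    "census_frame",
]


@dataclass
class ContactConfig:
    hydrophobic_cutoff: float = 6.5     # Å, side-chain COM to base COM
    electrostatic_cutoff: float = 11.0  # Å, charged-group COM to phosphate P
    hbond_da_cutoff: float = 3.5        # Å, donor-acceptor heavy-atom distance
    hbond_angle_min: float = 135.0      # degrees, only applied if H present
    population_threshold: float = 0.5
    hydrophobic_residues: frozenset[str] = chemistry.HYDROPHOBIC_RESIDUES
    charged_residues: frozenset[str] = chemistry.CHARGED_RESIDUES
    include_his: bool = False

    def __post_init__(self) -> None:
        for name in ("hydrophobic_cutoff", "electrostatic_cutoff", "hbond_da_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.population_threshold <= 1.0:
            raise ValueError("population_threshold must lie in [0, 1]")
        self.hydrophobic_residues = frozenset(self.hydrophobic_residues)
        charged = set(self.charged_residues)
        if self.include_his:
            charged.add("HIS")
        self.charged_residues = frozenset(charged)


@dataclass
class ContactSummary:
    """One (protein residue, nucleotide, class) record with per-frame presence."""

    contact_class: str                      # hbond | hydrophobic | electrostatic
    protein_partner: tuple[str, int, str]   # (chain, resid, resname)
    rna_partner: tuple[str, int, str]       # (chain, resid, base letter)
    present: np.ndarray = field(repr=False)  # per-frame bool

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)

    @property
    def population(self) -> float:
        return float(self.present.mean())

    @property
    def n_frames(self) -> int:
        return int(self.present.size)

    @property
    def pair_key(self) -> tuple[str, tuple, tuple]:
        return (self.contact_class, self.protein_partner, self.rna_partner)


def _protein_residues(topo: Topology):
    for (chain, resid, resname), idx in topo.residues():
        if topo.molecule_class[chain] == "protein":
            yield (chain, resid, resname), idx


def _nucleotides(topo: Topology):
    for (chain, resid, resname), idx in topo.residues():
        if topo.molecule_class[chain] == "rna":
            yield (chain, resid, normalize_base(resname)), idx


def _require_both_chains(topo: Topology) -> None:
    classes = set(topo.molecule_class.values())
    if "protein" not in classes or "rna" not in classes:
        raise ValueError(
            f"contact census needs both a protein and an RNA chain; found {sorted(classes)}"
        )


def _com_series(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    """(n_frames, 3) center-of-mass track of an atom group."""
    m = traj.topology.masses[idx]
    return np.einsum("fad,a->fd", traj.coords[:, idx, :], m) / m.sum()


def hydrophobic_contacts(traj: Trajectory, cfg: ContactConfig | None = None) -> list[ContactSummary]:
    """Side-chain-COM / base-COM proximity census over hydrophobic residues.

    Only pairs present in at least one frame are returned.
    """
    cfg = cfg or ContactConfig()
    topo = traj.topology
    _require_both_chains(topo)
    out: list[ContactSummary] = []
    nts = [(key, chemistry.base_atom_indices(topo, idx)) for key, idx in _nucleotides(topo)]
    for pkey, pidx in _protein_residues(topo):
        if pkey[2] not in cfg.hydrophobic_residues:
            continue
        sc = chemistry.sidechain_atom_indices(topo, pidx)
        if sc.size == 0:
            continue
        sc_com = _com_series(traj, sc)
        for nkey, base_idx in nts:
            if base_idx.size == 0:
                continue
            d = np.linalg.norm(sc_com - _com_series(traj, base_idx), axis=1)
            present = d < cfg.hydrophobic_cutoff
            if present.any():
                out.append(ContactSummary("hydrophobic", pkey, nkey, present))
    return out


def electrostatic_contacts(traj: Trajectory, cfg: ContactConfig | None = None) -> list[ContactSummary]:
    """Charged-group-COM / phosphate-P proximity census over Arg/Lys (+His optionally).

    Nucleotides without a backbone P atom (5' termini) are skipped.
    """
    cfg = cfg or ContactConfig()
    topo = traj.topology
    _require_both_chains(topo)
    out: list[ContactSummary] = []
    phosphates = []
    for nkey, idx in _nucleotides(topo):
        p = idx[topo.names[idx] == "P"]
        if p.size:
            phosphates.append((nkey, int(p[0])))
    for pkey, pidx in _protein_residues(topo):
        if pkey[2] not in cfg.charged_residues:
            continue
        grp = chemistry.charged_group_indices(topo, pidx, pkey[2])
        if grp.size == 0:
            continue
        grp_com = _com_series(traj, grp)
        for nkey, p_atom in phosphates:
            d = np.linalg.norm(grp_com - traj.coords[:, p_atom, :], axis=1)
            present = d < cfg.electrostatic_cutoff
            if present.any():
                out.append(ContactSummary("electrostatic", pkey, nkey, present))
    return out


def _attached_hydrogens(traj: Trajectory, res_idx: np.ndarray,
                        donor: int, bond_cutoff: float = 1.25) -> np.ndarray:
    """Hydrogens of the residue covalently attached to ``donor`` (first frame)."""
    h = res_idx[traj.topology.elements[res_idx] == "H"]
    if h.size == 0:
        return h
    d = np.linalg.norm(traj.coords[0, h, :] - traj.coords[0, donor, :], axis=1)
    return h[d < bond_cutoff]


def hydrogen_bonds(traj: Trajectory, cfg: ContactConfig | None = None) -> list[ContactSummary]:
    """Donor-acceptor census between protein residues and nucleotides.

    A residue-nucleotide pair is hydrogen bonded in a frame when any of its
    donor/acceptor heavy-atom pairs (either direction) is within the D-A
    cutoff and — if the donor carries a hydrogen in the topology — some
    attached hydrogen gives a D-H...A angle above the minimum.  Records are
    deduplicated to one per residue-nucleotide pair.
    """
    cfg = cfg or ContactConfig()
    topo = traj.topology
    _require_both_chains(topo)
    prot = [(key, idx, chemistry.donor_acceptor_indices(topo, idx, key[2]))
            for key, idx in _protein_residues(topo)]
    rna = []
    for key, idx in _nucleotides(topo):
        resname = topo.resnames[idx[0]]
        rna.append((key, idx, chemistry.donor_acceptor_indices(topo, idx, resname)))

    out: list[ContactSummary] = []
    for pkey, pidx, (p_don, p_acc) in prot:
        for nkey, nidx, (n_don, n_acc) in rna:
            present = np.zeros(traj.n_frames, dtype=bool)
            for donors, acceptors, d_res in ((p_don, n_acc, pidx), (n_don, p_acc, nidx)):
                for d_atom in donors:
                    if acceptors.size == 0:
                        continue
                    dist = np.linalg.norm(
                        traj.coords[:, acceptors, :] - traj.coords[:, [d_atom], :], axis=2)
                    hit = dist <= cfg.hbond_da_cutoff
                    hyds = _attached_hydrogens(traj, d_res, d_atom)
                    if hyds.size:
                        hit &= _angle_ok(traj, d_atom, hyds, acceptors, cfg.hbond_angle_min)
                    present |= hit.any(axis=1)
            if present.any():
                out.append(ContactSummary("hbond", pkey, nkey, present))
    return out


def _angle_ok(traj: Trajectory, donor: int, hydrogens: np.ndarray,
              acceptors: np.ndarray, angle_min: float) -> np.ndarray:
    """(n_frames, n_acceptors) mask: some attached H gives angle(D-H...A) >= min."""
    D = traj.coords[:, donor, :][:, None, None, :]
    H = traj.coords[:, hydrogens, :][:, :, None, :]
    A = traj.coords[:, acceptors, :][:, None, :, :]
    v1 = D - H
    v2 = A - H
    cosang = (v1 * v2).sum(axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1) + 1e-300)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return (ang >= angle_min).any(axis=1)


def filter_by_population(contacts: list[ContactSummary],
                         threshold: float = 0.5) -> list[ContactSummary]:
    """Keep contacts with population strictly greater than ``threshold``.

    Output is sorted by descending population, then by partner keys.
    """
    kept = [c for c in contacts if c.population > threshold]
    return sorted(kept, key=lambda c: (-c.population, c.protein_partner, c.rna_partner))


def census_frame(contacts: list[ContactSummary]) -> pd.DataFrame:
    """Tabulate a census: one row per contact record."""
    rows = [{
        "class": c.contact_class,
        "protein_chain": c.protein_partner[0],
        "protein_resid": c.protein_partner[1],
        "protein_resname": c.protein_partner[2],
        "rna_chain": c.rna_partner[0],
        "rna_resid": c.rna_partner[1],
        "base": c.rna_partner[2],
        "population": c.population,
        "n_frames": c.n_frames,
    } for c in contacts]
    cols = ["class", "protein_chain", "protein_resid", "protein_resname",
            "rna_chain", "rna_resid", "base", "population", "n_frames"]
    return pd.DataFrame(rows, columns=cols)


def compare_censuses(a: list[ContactSummary], b: list[ContactSummary]) -> pd.DataFrame:
    """Outer join of two censuses on (class, protein partner, RNA partner).

    Populations are 0 where a record is absent from one ensemble; ``status``
    marks each record common / a_only / b_only.
    """
    pa = {c.pair_key: c.population for c in a}
    pb = {c.pair_key: c.population for c in b}
    keys = sorted(set(pa) | set(pb))
    rows = []
    for key in keys:
        in_a, in_b = key in pa, key in pb
        status = "common" if (in_a and in_b) else ("a_only" if in_a else "b_only")
        cls, prot, rna = key
        rows.append({
            "class": cls,
            "protein_chain": prot[0], "protein_resid": prot[1], "protein_resname": prot[2],
            "rna_chain": rna[0], "rna_resid": rna[1], "base": rna[2],
            "population_a": pa.get(key, 0.0),
            "population_b": pb.get(key, 0.0),
            "status": status,
        })
    cols = ["class", "protein_chain", "protein_resid", "protein_resname",
            "rna_chain", "rna_resid", "base", "population_a", "population_b", "status"]
    return pd.DataFrame(rows, columns=cols)
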