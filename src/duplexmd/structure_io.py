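"""Topology/trajectory model, multi-model PDB I/O, atom selection, subsampling.

A trajectory is a fixed topology plus a stack of coordinate frames sampled at
a constant interval ``dt`` (ps).  Frames are timed ``t0, t0+dt, ...`` with
``t0 == dt`` by default, so a 50 ns run sampled every 10 ps holds 5000 frames
(t = 10, 20, ..., 50000 ps).

Multi-model PDB is the only on-disk trajectory format.  Parsing is delegated
to Biopython; writing emits the fixed-width dialect directly (single-frame
files carry no MODEL records, multi-frame files are MODEL/ENDMDL blocks).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "Selection",
    "ParseError",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "select",
    "subsample",
]

#: Atomic masses (Da) for the elements the analysis touches.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_RNA_BASES = {"A", "U", "G", "C"}


def normalize_base(resname: str) -> str | None:
    """Map an RNA residue name to its one-letter base identity.

    Accepts the bare one-letter names (A/U/G/C), the R-prefixed AMBER-style
    names (RA/RU/...) and 5'/3'-terminal variants (A5, RU3, ...).  Returns
    None if the name is not an RNA residue name.
    """
    name = resname.strip().upper()
    if name and name[-1] in "53":
        name = name[:-1]
    if name.startswith("R") and len(name) == 2:
        name = name[1:]
    return name if name in _RNA_BASES else None


class ParseError(ValueError):
    """A PDB record could not be parsed; carries the offending line number."""


class StructureError(ValueError):
    """The parsed structure violates a topology invariant."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str
    mass: float

    def __post_init__(self) -> None:
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element symbol")
        if self.mass <= 0:
            raise StructureError(f"atom {self.name}: non-positive mass {self.mass}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resid, self.name)


def _element_from_name(name: str) -> str:
    """Guess the element from a PDB atom name (first alphabetic character)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise StructureError(f"cannot infer element from atom name {name!r}")


class Topology:
    """Ordered atom list with residue grouping and per-chain molecule class.

    Every chain must be classifiable as protein or RNA from its residue-name
    vocabulary; an unknown residue name is a hard error rather than a silent
    skip.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        if not self.atoms:
            raise StructureError("topology has no atoms")
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if a.key in seen:
                raise StructureError(f"duplicate atom {a.key}")
            seen.add(a.key)
        # vectorized views used throughout the analysis layer
        self.names = np.array([a.name for a in self.atoms])
        self.resnames = np.array([a.resname for a in self.atoms])
        self.resids = np.array([a.resid for a in self.atoms])
        self.chains = np.array([a.chain for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.molecule_class: dict[str, str] = self._classify_chains()

    def _classify_chains(self) -> dict[str, str]:
        classes: dict[str, str] = {}
        for chain in dict.fromkeys(self.chains.tolist()):
            resnames = set(self.resnames[self.chains == chain].tolist())
            is_prot = resnames <= PROTEIN_RESNAMES
            is_rna = all(normalize_base(r) is not None for r in resnames)
            if is_prot and not is_rna:
                classes[chain] = "protein"
            elif is_rna and not is_prot:
                classes[chain] = "rna"
            else:
                unknown = sorted(
                    r for r in resnames
                    if r not in PROTEIN_RESNAMES and normalize_base(r) is None
                )
                raise StructureError(
                    f"chain {chain!r} is neither protein nor RNA "
                    f"(unknown residue names: {unknown or sorted(resnames)})"
                )
        return classes

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues(self) -> list[tuple[tuple[str, int, str], np.ndarray]]:
        """Group atoms by residue, in topology order.

        Returns a list of ((chain, resid, resname), atom-index array) pairs.
        """
        out: list[tuple[tuple[str, int, str], list[int]]] = []
        current: tuple[str, int, str] | None = None
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.resid, a.resname)
            if key != current:
                out.append((key, [i]))
                current = key
            else:
                out[-1][1].append(i)
        return [(key, np.array(idx)) for key, idx in out]

    def residue_atoms(self, chain: str, resid: int) -> np.ndarray:
        idx = np.flatnonzero((self.chains == chain) & (self.resids == resid))
        if idx.size == 0:
            raise KeyError(f"no residue {chain}:{resid} in topology")
        return idx

    def __len__(self) -> int:
        return self.n_atoms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self.atoms == other.atoms


@dataclass
class Trajectory:
    """A topology plus time-ordered coordinate frames (Å)."""

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    dt: float = 10.0    # ps
    t0: float | None = None  # ps; defaults to dt

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"{self.coords.shape[1]} coordinate triples per frame but "
                f"{self.topology.n_atoms} atoms in topology"
            )
        if self.coords.shape[0] < 1:
            raise StructureError("trajectory needs at least one frame")
        if self.dt <= 0:
            raise StructureError(f"dt must be positive, got {self.dt}")
        if self.t0 is None:
            self.t0 = self.dt

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps: t0, t0+dt, ..."""
        return self.t0 + self.dt * np.arange(self.n_frames)

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def with_coords(self, coords: np.ndarray, dt: float | None = None,
                    t0: float | None = None) -> "Trajectory":
        return Trajectory(self.topology, coords,
                          dt=self.dt if dt is None else dt,
                          t0=self.t0 if t0 is None else t0)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

class Selection:
    """Composable atom predicate.

    Field filters (chains, resid range, atom names, molecule class) combine
    by intersection inside one Selection; ``|`` and ``&`` build unions and
    intersections of Selections.  Applying a selection returns atom indices
    in topology order, so selection is idempotent and order-preserving by
    construction.
    """

    def __init__(self, chains: Iterable[str] | str | None = None,
                 resids: Iterable[int] | range | None = None,
                 names: Iterable[str] | str | None = None,
                 molecule_class: str | None = None):
        self.chains = {chains} if isinstance(chains, str) else (
            set(chains) if chains is not None else None)
        self.resids = set(resids) if resids is not None else None
        self.names = {names} if isinstance(names, str) else (
            set(names) if names is not None else None)
        if molecule_class is not None and molecule_class not in ("protein", "rna"):
            raise ValueError(f"molecule_class must be 'protein' or 'rna', got {molecule_class!r}")
        self.molecule_class = molecule_class

    def mask(self, topo: Topology) -> np.ndarray:
        m = np.ones(topo.n_atoms, dtype=bool)
        if self.chains is not None:
            m &= np.isin(topo.chains, sorted(self.chains))
        if self.resids is not None:
            m &= np.isin(topo.resids, sorted(self.resids))
        if self.names is not None:
            m &= np.isin(topo.names, sorted(self.names))
        if self.molecule_class is not None:
            ok = {c for c, cls in topo.molecule_class.items() if cls == self.molecule_class}
            m &= np.isin(topo.chains, sorted(ok))
        return m

    def __and__(self, other: "Selection") -> "Selection":
        return _Compound(np.logical_and, self, other)

    def __or__(self, other: "Selection") -> "Selection":
        return _Compound(np.logical_or, self, other)

    def __repr__(self) -> str:
        parts = [f"{k}={v!r}" for k, v in
                 (("chains", self.chains), ("resids", self.resids),
                  ("names", self.names), ("molecule_class", self.molecule_class))
                 if v is not None]
        return f"Selection({', '.join(parts)})"


class _Compound(Selection):
    def __init__(self, op, left: Selection, right: Selection):
        self._op, self._left, self._right = op, left, right

    def mask(self, topo: Topology) -> np.ndarray:
        return self._op(self._left.mask(topo), self._right.mask(topo))

    def __repr__(self) -> str:
        sym = "&" if self._op is np.logical_and else "|"
        return f"({self._left!r} {sym} {self._right!r})"


def select(topo: Topology, expr: Selection) -> np.ndarray:
    """Indices of atoms matching ``expr``, in topology order (may be empty)."""
    return np.flatnonzero(expr.mask(topo))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _validate_coordinate_fields(path: Path) -> None:
    """Pre-scan ATOM/HETATM records so a malformed coordinate field can be
    reported with its line number (the delegated parser loses that context)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi]
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: malformed coordinate field {fieldtxt!r}"
                        ) from None


def read_pdb(path: str | Path, dt: float | None = None, t0: float | None = None) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory.

    A file without MODEL records is a single frame.  ``dt`` is not stored in
    PDB files; if the caller does not supply it, 10 ps is assumed with a
    logged warning.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_coordinate_fields(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            structure = parser.get_structure("traj", str(path))
        except PDBConstructionException as exc:  # pragma: no cover - defensive
            raise ParseError(f"{path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise ParseError(f"{path}: no models found")

    def model_atoms(model):
        out = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    out.append((chain.id, residue.id[1], residue.resname.strip(),
                                atom.get_name(), atom.element or "", atom.coord))
        return out

    first = model_atoms(models[0])
    records = []
    for serial, (chain, resid, resname, name, element, _xyz) in enumerate(first, start=1):
        elem = element.strip().upper().capitalize() or _element_from_name(name)
        elem = elem if elem in ELEMENT_MASSES else _element_from_name(name)
        if elem not in ELEMENT_MASSES:
            raise StructureError(f"no mass for element {elem!r} (atom {name})")
        records.append(AtomRecord(serial=serial, name=name, resname=resname,
                                  resid=resid, chain=chain, element=elem,
                                  mass=ELEMENT_MASSES[elem]))
    topo = Topology(records)

    frames = np.empty((len(models), topo.n_atoms, 3), dtype=float)
    for k, model in enumerate(models):
        atoms = model_atoms(model)
        if len(atoms) != topo.n_atoms:
            raise StructureError(
                f"{path}: model {k + 1} has {len(atoms)} atoms, expected {topo.n_atoms}"
            )
        for i, (chain, resid, resname, name, _element, xyz) in enumerate(atoms):
            rec = topo.atoms[i]
            if (chain, resid, name) != rec.key:
                raise StructureError(
                    f"{path}: model {k + 1} atom {i + 1} is {(chain, resid, name)}, "
                    f"expected {rec.key}"
                )
            frames[k, i] = xyz

    if dt is None:
        logger.warning("%s: no sampling interval supplied; assuming dt = 10 ps", path)
        dt = 10.0
    return Trajectory(topo, frames, dt=dt, t0=t0)


def _format_atom_line(a: AtomRecord, xyz: np.ndarray) -> str:
    # PDB v3.3 fixed columns; names of <4 chars for 1-letter elements are
    # indented one space (" C5'"), 4-char names start at column 13.
    name = a.name
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    return (
        f"ATOM  {a.serial % 100000:5d} {name:<4s} {a.resname:>3s} {a.chain[:1]:1s}"
        f"{a.resid % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a fixed-width (multi-model) PDB file.

    Coordinates are written to 3 decimals, so a round trip preserves them to
    1e-3 Å.  Single-frame trajectories are written without MODEL records.
    """
    path = Path(path)
    lines: list[str] = []
    multi = traj.n_frames > 1
    for k in range(traj.n_frames):
        if multi:
            lines.append(f"MODEL     {k + 1:4d}")
        prev_chain = None
        for a, xyz in zip(traj.topology.atoms, traj.coords[k]):
            if prev_chain is not None and a.chain != prev_chain:
                lines.append("TER")
            lines.append(_format_atom_line(a, xyz))
            prev_chain = a.chain
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def subsample(traj: Trajectory, interval_ps: float) -> Trajectory:
    """Keep frames at times t0, t0+interval, ...; the frame at t0 is always kept.

    ``interval_ps`` must be a positive integer multiple of ``traj.dt``.
    """
    if interval_ps <= 0:
        raise ValueError(f"interval must be positive, got {interval_ps}")
    stride = interval_ps / traj.dt
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError(
            f"interval {interval_ps} ps is not an integer multiple of dt = {traj.dt} ps"
        )
    stride = int(round(stride))
    return Trajectory(traj.topology, traj.coords[::stride],
                      dt=traj.dt * stride, t0=traj.t0)
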