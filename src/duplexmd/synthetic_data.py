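"""Seeded generators for coarse structures and trajectories.

These generators produce idealized protein-RNA systems carrying the
statistical structure the analysis layer assumes — an A-form-like 13-bp
duplex, protein residues parked at controlled distances, Gaussian positional
jitter, and a programmed, terminally-ordered exponential strand-opening
schedule.  The structures are deliberately coarse: only the atoms the
analysis touches (P, C5', base heavy atoms, protein backbone plus side-chain
pseudo-atoms) are emitted, with standard PDB naming so selections behave as
on real files.  Nothing here is stereochemically valid RNA; chemistry is not
what is under test.

All generators are pure functions of (spec, seed): identical inputs yield
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .structure_io import AtomRecord, ELEMENT_MASSES, Topology, Trajectory
from .duplex import PairMap

__all__ = [
    "DuplexSpec",
    "OpeningEvent",
    "MotionSpec",
    "ResiduePlacement",
    "DomainSpec",
    "make_duplex",
    "duplex_pair_map",
    "make_protein_patch",
    "make_trajectory",
    "make_qb_trace",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Five base heavy atoms per base letter (a coarse ring proxy).
_BASE_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5"),
    "U": ("N1", "C2", "N3", "C4", "C5"),
}

#: Heavy side-chain atoms emitted for each supported residue.
_SIDECHAIN_ATOMS = {
    "GLY": (),
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "PRO": ("CB", "CG", "CD"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "CYS": ("CB", "SG"),
}

_CHARGED_GROUP = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}


@dataclass
class DuplexSpec:
    """Idealized antiparallel RNA duplex on a regular helix.

    ``sequence`` is strand A read 5'->3'; strand B is its complement.  The
    paired base centers of mass sit ``pair_distance`` apart, perpendicular
    to the helix axis.
    """

    n_bp: int = 13
    sequence: str | None = None     # defaults to alternating AU/GC pattern
    rise: float = 2.81              # Å per bp along the axis (A-form-like)
    twist: float = 32.7             # degrees per bp
    pair_distance: float = 5.5      # Å between paired base COMs
    backbone_offset: float = 4.0    # Å from base COM out to C5'

    def __post_init__(self) -> None:
        if self.n_bp < 2:
            raise ValueError("n_bp must be >= 2")
        if self.sequence is None:
            pattern = "AUGC"
            self.sequence = "".join(pattern[i % 4] for i in range(self.n_bp))
        self.sequence = self.sequence.upper()
        if len(self.sequence) != self.n_bp:
            raise ValueError("sequence length must equal n_bp")
        if any(b not in _COMPLEMENT for b in self.sequence):
            raise ValueError(f"sequence contains non-RNA letters: {self.sequence}")


@dataclass
class OpeningEvent:
    """Programmed opening of one base pair: the strand-B nucleotide moves
    along the pair axis by extra * (1 - exp(-t/tau))."""

    pair_index: int   # 1-based, counted from the strand-A 5' terminus
    extra: float      # Å of additional separation at t = infinity
    tau_ns: float

    def __post_init__(self) -> None:
        if self.tau_ns <= 0:
            raise ValueError("tau must be positive")


@dataclass
class MotionSpec:
    n_frames: int = 100
    dt: float = 10.0                 # ps
    jitter_sigma: float = 0.3        # Å, isotropic per atom per frame
    opening: list[OpeningEvent] = field(default_factory=list)
    drift_rotation_deg: float = 0.0  # per frame, about z through the COM
    drift_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # per frame
    seed: int = 0


@dataclass
class ResiduePlacement:
    """One coarse residue anchored near a nucleotide.

    ``anchor_atom`` selects the reference point: "base" (base COM; the
    side-chain COM lands exactly ``offset`` Å away) or "P" (backbone
    phosphorus; the charged-group COM lands exactly ``offset`` Å away).
    """

    resname: str
    resid: int
    anchor: tuple[str, int]   # (chain, resid) of the anchor nucleotide
    offset: float             # Å
    anchor_atom: str = "base"

    def __post_init__(self) -> None:
        if self.resname not in _SIDECHAIN_ATOMS:
            raise ValueError(f"unsupported residue {self.resname}")
        if self.offset <= 0:
            raise ValueError("offset must be positive")
        if self.anchor_atom not in ("base", "P"):
            raise ValueError("anchor_atom must be 'base' or 'P'")


@dataclass
class DomainSpec:
    residues: list[ResiduePlacement]
    chain: str = "K"


def _mass_of(name: str) -> tuple[str, float]:
    elem = name[0] if name[0] in ELEMENT_MASSES else name[0].upper()
    return elem, ELEMENT_MASSES[elem]


def _balanced_cluster(center: np.ndarray, names: tuple[str, ...],
                      plane_u: np.ndarray, plane_v: np.ndarray,
                      radius: float = 0.7) -> list[tuple[str, np.ndarray]]:
    """Place atoms on a regular polygon whose mass-weighted COM is exactly
    ``center`` (polygon offsets are re-centered by mass)."""
    n = len(names)
    angles = 2 * np.pi * np.arange(n) / n
    offsets = radius * (np.outer(np.cos(angles), plane_u) + np.outer(np.sin(angles), plane_v))
    masses = np.array([_mass_of(nm)[1] for nm in names])
    offsets -= (masses[:, None] * offsets).sum(axis=0) / masses.sum()
    return [(nm, center + off) for nm, off in zip(names, offsets)]


def make_duplex(spec: DuplexSpec | None = None) -> Trajectory:
    """Build a single-frame idealized duplex trajectory.

    Chains are "A" (mRNA-like) and "B" (miRNA-like), each with resids
    1..n_bp numbered 5'->3'; nucleotide i of chain A pairs nucleotide
    n_bp+1-i of chain B.  Each nucleotide carries P (except the 5' terminus),
    C5', and five base heavy atoms whose COM realizes the pair geometry.
    """
    spec = spec or DuplexSpec()
    n = spec.n_bp
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1

    def axis_frame(i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        theta = np.radians(spec.twist) * i
        u = np.array([np.cos(theta), np.sin(theta), 0.0])   # pair axis
        w = np.array([-np.sin(theta), np.cos(theta), 0.0])  # in-plane normal
        c = np.array([0.0, 0.0, spec.rise * i])
        return c, u, w

    z = np.array([0.0, 0.0, 1.0])

    def emit(chain: str, resid: int, base: str, pair_i: int, side: float) -> None:
        nonlocal serial
        c, u, w = axis_frame(pair_i)
        base_com = c + side * (spec.pair_distance / 2.0) * u
        c5 = c + side * (spec.pair_distance / 2.0 + spec.backbone_offset) * u + 0.5 * w
        p = c + side * (spec.pair_distance / 2.0 + spec.backbone_offset + 1.5) * u - 0.8 * w + 0.6 * z

        def add(name: str, xyz: np.ndarray) -> None:
            nonlocal serial
            elem, mass = _mass_of(name)
            records.append(AtomRecord(serial=serial, name=name, resname=base,
                                      resid=resid, chain=chain, element=elem, mass=mass))
            coords.append(xyz)
            serial += 1

        if resid != 1:  # no 5'-terminal phosphate
            add("P", p)
        add("C5'", c5)
        for name, xyz in _balanced_cluster(base_com, _BASE_ATOMS[base], u, w):
            add(name, xyz)

    for i in range(n):                       # strand A, 5'->3'
        emit("A", i + 1, spec.sequence[i], i, -1.0)
    for j in range(n):                       # strand B, 5'->3'; B_j pairs A_{n+1-j}
        pair_i = n - 1 - j
        emit("B", j + 1, _COMPLEMENT[spec.sequence[pair_i]], pair_i, +1.0)

    topo = Topology(records)
    return Trajectory(topo, np.array(coords)[None, :, :], dt=10.0)


def duplex_pair_map(n_bp: int = 13) -> PairMap:
    """Pair i: (A, i) with (B, n_bp+1-i), indices counted from A's 5' end."""
    return PairMap(tuple((("A", i), ("B", n_bp + 1 - i)) for i in range(1, n_bp + 1)))


def make_protein_patch(spec: DomainSpec, duplex: Trajectory) -> Trajectory:
    """Merge coarse protein residues, placed at stated offsets from anchor
    nucleotides, into a single-frame structure.

    Raises a placement error when a new atom lands within 1 Å of an existing
    one.
    """
    from . import chemistry

    topo = duplex.topology
    frame = duplex.coords[0]
    axis_dir = np.array([0.0, 0.0, 1.0])
    records = list(topo.atoms)
    coords = [xyz for xyz in frame]
    serial = max(a.serial for a in records) + 1

    for place in spec.residues:
        chain_r, resid_r = place.anchor
        res_idx = topo.residue_atoms(chain_r, resid_r)
        if place.anchor_atom == "P":
            p = res_idx[topo.names[res_idx] == "P"]
            if p.size == 0:
                raise ValueError(f"anchor {place.anchor} has no P atom")
            anchor = frame[p[0]]
        else:
            bidx = chemistry.base_atom_indices(topo, res_idx)
            m = topo.masses[bidx]
            anchor = (frame[bidx] * m[:, None]).sum(axis=0) / m.sum()
        # outward: radially away from the helix axis (z), lifted out of the
        # helical plane so the approach clears the anchor's own backbone
        radial = anchor - axis_dir * np.dot(anchor, axis_dir)
        norm = np.linalg.norm(radial)
        radial_u = radial / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
        direction = radial_u + 0.9 * axis_dir
        direction /= np.linalg.norm(direction)
        perp = np.cross(axis_dir, radial_u)

        target = anchor + place.offset * direction
        sc_names = _SIDECHAIN_ATOMS[place.resname]
        new_atoms: list[tuple[str, np.ndarray]] = []
        charged = _CHARGED_GROUP.get(place.resname)
        if place.anchor_atom == "P" and charged:
            group = tuple(charged)
            rest = tuple(nm for nm in sc_names if nm not in charged)
            new_atoms += _balanced_cluster(target, group, direction, perp)
            for k, nm in enumerate(rest):
                new_atoms.append((nm, target + (1.5 + 0.8 * k) * direction + 0.3 * k * perp))
        elif sc_names:
            new_atoms += _balanced_cluster(target, sc_names, direction, perp, radius=0.9)
        # backbone beyond the side chain (CA doubles as the side-chain proxy for Gly)
        bb_base = target if not sc_names else target + 3.0 * direction
        for k, nm in enumerate(("CA", "N", "C", "O")):
            off = np.zeros(3) if (nm == "CA" and not sc_names) else (
                (1.0 + 0.9 * k) * direction + 0.7 * ((-1) ** k) * perp + 0.3 * k * axis_dir)
            new_atoms.append((nm, bb_base + off))

        existing = np.array(coords)
        for nm, xyz in new_atoms:
            if np.min(np.linalg.norm(existing - xyz, axis=1)) < 1.0:
                raise ValueError(
                    f"placement clash: {place.resname}{place.resid} atom {nm} "
                    f"within 1 Å of an existing atom")
        order = ("N", "CA", "C", "O") + tuple(sc_names)
        new_atoms.sort(key=lambda t: order.index(t[0]))
        for nm, xyz in new_atoms:
            elem, mass = _mass_of(nm)
            records.append(AtomRecord(serial=serial, name=nm, resname=place.resname,
                                      resid=place.resid, chain=spec.chain,
                                      element=elem, mass=mass))
            coords.append(xyz)
            serial += 1

    return Trajectory(Topology(records), np.array(coords)[None, :, :],
                      dt=duplex.dt, t0=duplex.t0)


def make_trajectory(structure: Trajectory, motion: MotionSpec) -> Trajectory:
    """Animate a single-frame structure: Gaussian jitter, programmed
    exponential pair opening, optional rigid drift.

    Frame k (k = 0..n_frames-1, time t_k = (k+1) dt) is the input structure
    plus isotropic jitter(sigma), plus — for each opening event — a
    displacement of the strand-B nucleotide of that pair along the pair axis
    by extra * (1 - exp(-t_k / tau)), plus the cumulative rigid drift.
    """
    rng = np.random.default_rng(motion.seed)
    topo = structure.topology
    base = structure.coords[0]
    n_atoms = topo.n_atoms
    times = motion.dt * np.arange(1, motion.n_frames + 1)  # ps

    # resolve opening events against the antiparallel A/B pair map
    events: list[tuple[np.ndarray, np.ndarray, float, float]] = []
    if motion.opening:
        rna_chains = [c for c, cls in topo.molecule_class.items() if cls == "rna"]
        if len(rna_chains) != 2:
            raise ValueError("opening schedule needs exactly two RNA chains")
        pmap = PairMap.antiparallel(topo, rna_chains[0], rna_chains[1])
        from . import chemistry
        for ev in motion.opening:
            if not 1 <= ev.pair_index <= len(pmap):
                raise ValueError(f"pair index {ev.pair_index} outside 1..{len(pmap)}")
            k1, k2 = pmap.pairs[ev.pair_index - 1]
            idx1 = topo.residue_atoms(*k1)
            idx2 = topo.residue_atoms(*k2)
            b1 = chemistry.base_atom_indices(topo, idx1)
            b2 = chemistry.base_atom_indices(topo, idx2)
            com1 = base[b1].mean(axis=0)
            com2 = base[b2].mean(axis=0)
            axis = com2 - com1
            axis /= np.linalg.norm(axis)
            events.append((idx2, axis, ev.extra, ev.tau_ns * 1000.0))

    frames = np.empty((motion.n_frames, n_atoms, 3))
    com = base.mean(axis=0)
    for k, t in enumerate(times):
        x = base.copy()
        for idx2, axis, extra, tau_ps in events:
            x[idx2] += axis * extra * (1.0 - np.exp(-t / tau_ps))
        if motion.drift_rotation_deg or any(motion.drift_translation):
            ang = np.radians(motion.drift_rotation_deg) * (k + 1)
            ca, sa = np.cos(ang), np.sin(ang)
            R = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
            x = (x - com) @ R.T + com + np.asarray(motion.drift_translation) * (k + 1)
        if motion.jitter_sigma > 0:
            x = x + rng.normal(0.0, motion.jitter_sigma, size=(n_atoms, 3))
        frames[k] = x
    return Trajectory(topo, frames, dt=motion.dt)


def make_qb_trace(A: float, tau_ns: float, B: float, n: int = 5000,
                  dt_ps: float = 10.0, sigma: float = 0.0,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Sample y_k = A exp(-t_k/tau) + B + N(0, sigma^2) at t_k = k dt.

    Returns (times_ps, y); times start at dt_ps.
    """
    if n < 4:
        raise ValueError("need at least 4 samples")
    t_ps = dt_ps * np.arange(1, n + 1)
    y = A * np.exp(-(t_ps / 1000.0) / tau_ns) + B
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, size=n)
    return t_ps, y


def spec_dict(spec) -> dict:
    """JSON-ready dict of any generator spec (for provenance sidecars)."""
    return asdict(spec)
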