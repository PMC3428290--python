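"""Base-pair geometry of the RNA duplex.

Per-pair inter-strand distance traces (between base-moiety mass centers),
residue-to-base distance series, the holo-vs-apo pairwise distance-
difference landscape, and strand-opening detection with a sustained-
excursion rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import chemistry
from .geometry import DescriptorSeries
from .structure_io import Selection, Topology, Trajectory, select

__all__ = [
    "PairMap",
    "BasePairSeries",
    "OpeningReport",
    "basepair_distances",
    "residue_base_distance",
    "distance_difference_landscape",
    "detect_opening",
]

NucleotideKey = tuple[str, int]  # (chain, resid)


@dataclass(frozen=True)
class PairMap:
    """Ordered base-pair assignment: (strand-1 key, strand-2 key) per pair.

    Pair indices run 1..n in list order, counted from the declared terminus.
    """

    pairs: tuple[tuple[NucleotideKey, NucleotideKey], ...]

    def __post_init__(self) -> None:
        seen: set[NucleotideKey] = set()
        for s1, s2 in self.pairs:
            for key in (s1, s2):
                if key in seen:
                    raise ValueError(f"nucleotide {key} appears in more than one pair")
                seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def antiparallel(cls, topo: Topology, chain1: str, chain2: str) -> "PairMap":
        """Infer pairing by position: i-th nucleotide of strand 1 with the
        i-th-from-last nucleotide of strand 2."""
        r1 = [resid for (c, resid, _), _ in topo.residues() if c == chain1]
        r2 = [resid for (c, resid, _), _ in topo.residues() if c == chain2]
        if len(r1) != len(r2):
            raise ValueError(
                f"strands differ in length: {len(r1)} ({chain1}) vs {len(r2)} ({chain2})")
        return cls(tuple(((chain1, a), (chain2, b)) for a, b in zip(r1, r2[::-1])))


@dataclass
class BasePairSeries:
    """Inter-strand base-COM distance (Å) of one pair over the trajectory."""

    pair_index: int
    times: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError("one distance per frame required")


@dataclass
class OpeningReport:
    """Per-pair opening verdicts and the terminal-first ordering flag."""

    opened: list[bool]
    opening_times: list[float | None]  # ps
    threshold: list[float]             # Å, baseline + delta per pair
    ordered_from_terminus: bool


def _base_com_track(traj: Trajectory, key: NucleotideKey) -> np.ndarray:
    chain, resid = key
    idx = traj.topology.residue_atoms(chain, resid)
    base_idx = chemistry.base_atom_indices(traj.topology, idx)
    if base_idx.size == 0:
        raise ValueError(f"nucleotide {chain}:{resid} has no base heavy atoms")
    m = traj.topology.masses[base_idx]
    return np.einsum("fad,a->fd", traj.coords[:, base_idx, :], m) / m.sum()


def basepair_distances(traj: Trajectory, pairs: PairMap) -> list[BasePairSeries]:
    """Distance between the base-moiety mass centers of each mapped pair, per frame."""
    out = []
    for i, (k1, k2) in enumerate(pairs.pairs, start=1):
        try:
            d = np.linalg.norm(_base_com_track(traj, k1) - _base_com_track(traj, k2), axis=1)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"pair {i} ({k1} - {k2}): {exc}") from exc
        out.append(BasePairSeries(pair_index=i, times=traj.times, distances=d))
    return out


def residue_base_distance(traj: Trajectory, residue: NucleotideKey,
                          bases: list[NucleotideKey],
                          label: str = "residue_base_distance") -> DescriptorSeries:
    """Distance from a protein residue's side-chain COM to the joint COM of
    the listed bases, per frame."""
    topo = traj.topology
    chain, resid = residue
    res_idx = topo.residue_atoms(chain, resid)
    sc = chemistry.sidechain_atom_indices(topo, res_idx)
    if sc.size == 0:
        raise ValueError(f"residue {chain}:{resid} has no side-chain atoms")
    base_idx = np.concatenate([
        chemistry.base_atom_indices(topo, topo.residue_atoms(c, r)) for c, r in bases])
    if base_idx.size == 0:
        raise ValueError(f"no base heavy atoms among {bases}")
    m_sc = topo.masses[sc]
    m_b = topo.masses[base_idx]
    sc_com = np.einsum("fad,a->fd", traj.coords[:, sc, :], m_sc) / m_sc.sum()
    b_com = np.einsum("fad,a->fd", traj.coords[:, base_idx, :], m_b) / m_b.sum()
    d = np.linalg.norm(sc_com - b_com, axis=1)
    return DescriptorSeries(times=traj.times, values=d, label=label)


def distance_difference_landscape(holo: Trajectory, apo: Trajectory,
                                  sel_atom: str = "C5'") -> tuple[list[NucleotideKey], np.ndarray]:
    """Pairwise time-mean distance difference matrix between two ensembles.

    Entry (i, j) is mean_t d_holo(atom_i, atom_j) - mean_t d_apo(atom_i, atom_j)
    over the named atom (one per nucleotide, e.g. C5').  Symmetric with a
    zero diagonal; positive entries mark nucleotide pairs further apart in
    the holo ensemble.
    """
    def atom_map(traj: Trajectory) -> dict[NucleotideKey, int]:
        topo = traj.topology
        idx = select(topo, Selection(names=sel_atom, molecule_class="rna"))
        return {(topo.chains[i], int(topo.resids[i])): int(i) for i in idx}

    mh, ma = atom_map(holo), atom_map(apo)
    if set(mh) != set(ma):
        raise ValueError(
            f"nucleotide sets differ: {sorted(set(mh) ^ set(ma))} not shared")
    keys = sorted(mh)

    def mean_dist(traj: Trajectory, amap: dict[NucleotideKey, int]) -> np.ndarray:
        X = traj.coords[:, [amap[k] for k in keys], :]
        diff = X[:, :, None, :] - X[:, None, :, :]
        return np.linalg.norm(diff, axis=-1).mean(axis=0)

    return keys, mean_dist(holo, mh) - mean_dist(apo, ma)


def detect_opening(series: list[BasePairSeries], baseline: list[float] | np.ndarray,
                   delta: float = 3.0, sustain: int = 50) -> OpeningReport:
    """Sustained-excursion opening detector.

    A pair opens at the first frame where its distance exceeds baseline +
    delta for at least ``sustain`` consecutive frames.  The ordering flag is
    true iff opening times are non-decreasing with pair index (pairs counted
    from the declared terminus), unopened pairs following all opened ones.
    """
    if sustain < 1:
        raise ValueError("sustain must be >= 1")
    if delta <= 0:
        raise ValueError("delta must be positive")
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size != len(series):
        raise ValueError("one baseline per pair required")
    opened: list[bool] = []
    times: list[float | None] = []
    thresholds: list[float] = []
    for s, b in zip(series, baseline):
        thr = b + delta
        thresholds.append(thr)
        above = s.distances > thr
        t_open: float | None = None
        run = 0
        for f, a in enumerate(above):
            run = run + 1 if a else 0
            if run >= sustain:
                t_open = float(s.times[f - sustain + 1])
                break
        opened.append(t_open is not None)
        times.append(t_open)

    ordered = True
    last = -np.inf
    seen_unopened = False
    for o, t in zip(opened, times):
        if not o:
            seen_unopened = True
            continue
        if seen_unopened or t < last:
            ordered = False
            break
        last = t
    return OpeningReport(opened=opened, opening_times=times,
                         threshold=thresholds, ordered_from_terminus=ordered)
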