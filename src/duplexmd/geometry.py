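"""Rigid-body superposition and per-frame/per-atom structural descriptors.

RMSD series, RMSF profiles and radii of gyration are the order parameters
used downstream as free-energy-landscape coordinates and stability measures.
Conventions: RMSD/RMSF are unweighted over the selected atoms (the typical
selection is a single atom type such as C5' or CA; a mass-weighting flag is
available); Rg is mass-weighted.  The superposition set equals the
measurement set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Selection, Topology, Trajectory, select

__all__ = [
    "TransformResult",
    "DescriptorSeries",
    "FluctuationProfile",
    "DegenerateGeometryError",
    "kabsch",
    "superpose",
    "rmsd",
    "rmsd_series",
    "average_structure",
    "rmsf",
    "radius_of_gyration",
    "center_of_mass",
]


class DegenerateGeometryError(ValueError):
    """Superposition target is collinear/coincident and the rotation is ill-defined."""


@dataclass(frozen=True)
class TransformResult:
    """Proper rigid motion x -> rotation @ x + translation, with its residual RMSD (Å)."""

    rotation: np.ndarray   # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DescriptorSeries:
    """A per-frame scalar descriptor (Å) with its time base (ps)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class FluctuationProfile:
    """Per-atom RMS fluctuation about the time-average position (Å)."""

    keys: list[tuple[str, int, str]]  # (chain, resid, name)
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.keys) != self.values.size:
            raise ValueError("one fluctuation per atom key required")


def center_of_mass(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted mean position; unit masses if none given."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    if masses is None:
        return coords.mean(axis=0)
    masses = np.asarray(masses, dtype=float)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None) -> TransformResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (reflections excluded) and translation that
    minimize the weighted RMSD, together with that minimal RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"coordinate sets differ in shape: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[0] < 3 or mobile.shape[1] != 3:
        raise ValueError("need >= 3 points of dimension 3")
    w = np.ones(len(mobile)) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    cm = (mobile * w[:, None]).sum(axis=0) / wsum
    cr = (reference * w[:, None]).sum(axis=0) / wsum
    am = mobile - cm
    ar = reference - cr
    # collinearity check: second singular value of the centered reference
    if np.linalg.matrix_rank(ar * np.sqrt(w)[:, None], tol=1e-8) < 2:
        raise DegenerateGeometryError("points are collinear or coincident")
    rot, rssd = Rotation.align_vectors(ar, am, weights=w)
    R = rot.as_matrix()
    res = np.sqrt(max(rssd**2 / wsum, 0.0))
    return TransformResult(rotation=R, translation=cr - cm @ R.T, rmsd=float(res))


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None) -> np.ndarray:
    """``mobile`` after the optimal rigid fit onto ``reference``."""
    return kabsch(mobile, reference, weights).apply(mobile)


def rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Plain (no superposition) weighted RMSD between two coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w = np.ones(len(a)) if weights is None else np.asarray(weights, dtype=float)
    d2 = ((a - b) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def _selected(traj: Trajectory, sel: Selection) -> np.ndarray:
    idx = select(traj.topology, sel)
    if idx.size == 0:
        raise ValueError(f"selection matches no atoms: {sel!r}")
    return idx


def rmsd_series(traj: Trajectory, ref: np.ndarray, sel: Selection,
                mass_weighted: bool = False, label: str = "rmsd") -> DescriptorSeries:
    """Per-frame RMSD to ``ref`` after superposing each frame onto it.

    ``ref`` is a full-topology coordinate set (e.g. the average structure);
    both fit and measurement use the selected atoms.
    """
    idx = _selected(traj, sel)
    ref = np.asarray(ref, dtype=float)
    ref_sel = ref[idx] if ref.shape[0] == traj.topology.n_atoms else ref
    if ref_sel.shape[0] != idx.size:
        raise ValueError("reference does not cover the selection")
    w = traj.topology.masses[idx] if mass_weighted else None
    vals = np.array([kabsch(traj.coords[k][idx], ref_sel, w).rmsd
                     for k in range(traj.n_frames)])
    return DescriptorSeries(times=traj.times, values=vals, label=label)


def average_structure(traj: Trajectory, sel: Selection,
                      mass_weighted: bool = False,
                      tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Iterative superposition mean of the selected coordinates.

    All frames are superposed onto the running mean (seeded with the first
    frame) and the mean recomputed, until it moves by less than ``tol`` Å
    (max atom displacement).  Returns coordinates for the selected atoms.
    """
    idx = _selected(traj, sel)
    X = traj.coords[:, idx, :]
    w = traj.topology.masses[idx] if mass_weighted else None
    mean = X[0].copy()
    if traj.n_frames == 1:
        return mean
    for _ in range(max_iter):
        fitted = np.array([superpose(x, mean, w) for x in X])
        new_mean = fitted.mean(axis=0)
        shift = np.abs(new_mean - mean).max()
        mean = new_mean
        if shift < tol:
            return mean
    raise RuntimeError(
        f"average structure did not converge in {max_iter} iterations "
        f"(last mean shift {shift:.3e} Å > tol {tol:g} Å)"
    )


def rmsf(traj: Trajectory, sel: Selection, mass_weighted: bool = False) -> FluctuationProfile:
    """Per-atom RMS fluctuation about the iterated mean structure.

    Frames are first superposed (over the selection) onto the converged
    average structure; the fluctuation of atom i is the RMS of its distance
    to its time-averaged position.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    idx = _selected(traj, sel)
    w = traj.topology.masses[idx] if mass_weighted else None
    mean = average_structure(traj, sel, mass_weighted=mass_weighted)
    fitted = np.array([superpose(traj.coords[k][idx], mean, w)
                       for k in range(traj.n_frames)])
    mean_pos = fitted.mean(axis=0)
    fluct = np.sqrt(((fitted - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    keys = [traj.topology.atoms[i].key for i in idx]
    return FluctuationProfile(keys=keys, values=fluct)


def radius_of_gyration(frame: np.ndarray, sel: Selection | np.ndarray,
                       topo: Topology | None = None,
                       masses: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance of the selected atoms from their center of mass."""
    frame = np.asarray(frame, dtype=float)
    if isinstance(sel, Selection):
        if topo is None:
            raise ValueError("topology required to resolve a Selection")
        idx = select(topo, sel)
        if masses is None:
            masses = topo.masses[idx]
    else:
        idx = np.asarray(sel)
    if idx.size == 0:
        raise ValueError("empty selection")
    X = frame[idx]
    m = np.ones(len(X)) if masses is None else np.asarray(masses, dtype=float)
    com = center_of_mass(X, m)
    return float(np.sqrt((m * ((X - com) ** 2).sum(axis=1)).sum() / m.sum()))


def rg_series(traj: Trajectory, sel: Selection, label: str = "rg") -> DescriptorSeries:
    """Radius of gyration per frame over the selection."""
    idx = _selected(traj, sel)
    m = traj.topology.masses[idx]
    vals = np.array([radius_of_gyration(traj.coords[k], idx, masses=m)
                     for k in range(traj.n_frames)])
    return DescriptorSeries(times=traj.times, values=vals, label=label)
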