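"""Native-contact decay kinetics of duplex strand separation.

The fraction of native inter-strand contacts, Qb(t), measures how much of
the reference (closed-duplex) interface survives at time t: native contacts
are the inter-strand heavy-atom pairs within a cutoff (default 4.5 Å) in a
reference frame, and a native pair counts as retained in frame t while its
distance stays within a tolerance factor (default 1.2x) of its reference
distance.  Strand opening shows up as a decay of Qb toward a plateau and is
summarized by fitting the single-exponential model

    Qb(t) = A exp(-t / tau) + B

whose time constant tau is the opening time scale (a half-life
t_1/2 = tau ln 2 is also reported).  The fit is exposed statsmodels-style:
``ExponentialDecayModel(t, y).fit()`` returns an ``ExpFitResults`` with the
estimates, residual sum of squares and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .structure_io import Topology, Trajectory

__all__ = [
    "NativeContact",
    "QbSeries",
    "ExpFitResults",
    "ExponentialDecayModel",
    "native_contacts",
    "qb_series",
    "fit_exponential",
]


@dataclass(frozen=True)
class NativeContact:
    atom_i: int
    atom_j: int
    ref_distance: float  # Å


@dataclass
class QbSeries:
    times: np.ndarray          # ps
    qb: np.ndarray             # fraction in [0, 1]
    native: list[NativeContact] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.qb = np.asarray(self.qb, dtype=float)
        if self.times.shape != self.qb.shape:
            raise ValueError("one qb value per frame required")


def _rna_strands(topo: Topology) -> tuple[str, str]:
    rna = [c for c, cls in topo.molecule_class.items() if cls == "rna"]
    if len(rna) != 2:
        raise ValueError(f"expected exactly 2 RNA chains, found {rna}")
    return rna[0], rna[1]


def native_contacts(topo: Topology, reference: np.ndarray, cutoff: float = 4.5,
                    chains: tuple[str, str] | None = None) -> list[NativeContact]:
    """Inter-strand heavy-atom pairs within ``cutoff`` in the reference frame.

    Pairs within one strand are excluded.  An empty list (with a logged
    warning) is returned when the strands do not touch.
    """
    import logging
    reference = np.asarray(reference, dtype=float)
    c1, c2 = chains if chains is not None else _rna_strands(topo)
    heavy = topo.elements != "H"
    idx1 = np.flatnonzero((topo.chains == c1) & heavy)
    idx2 = np.flatnonzero((topo.chains == c2) & heavy)
    if idx1.size == 0 or idx2.size == 0:
        raise ValueError(f"chains {c1}/{c2} contain no heavy atoms")
    d = np.linalg.norm(reference[idx1][:, None, :] - reference[idx2][None, :, :], axis=2)
    ii, jj = np.nonzero(d < cutoff)
    out = [NativeContact(int(idx1[i]), int(idx2[j]), float(d[i, j]))
           for i, j in zip(ii, jj)]
    if not out:
        logging.getLogger(__name__).warning(
            "no native contacts between chains %s and %s at cutoff %.2f Å", c1, c2, cutoff)
    return out


def qb_series(traj: Trajectory, native: list[NativeContact],
              tolerance_factor: float = 1.2) -> QbSeries:
    """Fraction of native pairs retained per frame.

    A pair is retained while its distance is at most ``tolerance_factor``
    times its reference distance.
    """
    if not native:
        raise ValueError("native contact list is empty")
    i = np.array([c.atom_i for c in native])
    j = np.array([c.atom_j for c in native])
    ref = np.array([c.ref_distance for c in native])
    d = np.linalg.norm(traj.coords[:, i, :] - traj.coords[:, j, :], axis=2)
    qb = (d <= tolerance_factor * ref).mean(axis=1)
    return QbSeries(times=traj.times, qb=qb, native=list(native))


# ---------------------------------------------------------------------------
# single-exponential decay model
# ---------------------------------------------------------------------------

@dataclass
class ExpFitResults:
    """Estimates for Qb(t) = A exp(-t/tau) + B with fit diagnostics.

    ``tau`` is in the unit of the fitted time axis (ns in the pipeline);
    ``t_half = tau ln 2``.
    """

    A: float
    tau: float
    B: float
    rss: float
    converged: bool
    n_obs: int
    nfev: int = 0

    @property
    def t_half(self) -> float:
        return self.tau * np.log(2.0)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.A, self.tau, self.B])

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A * np.exp(-t / self.tau) + self.B

    def summary(self) -> str:
        lines = [
            "Single-exponential decay fit: y = A exp(-t/tau) + B",
            "-" * 51,
            f"{'n observations':<20}{self.n_obs:>12d}",
            f"{'A (amplitude)':<20}{self.A:>12.6g}",
            f"{'tau':<20}{self.tau:>12.6g}",
            f"{'t_half = tau ln 2':<20}{self.t_half:>12.6g}",
            f"{'B (offset)':<20}{self.B:>12.6g}",
            f"{'RSS':<20}{self.rss:>12.6g}",
            f"{'converged':<20}{str(self.converged):>12}",
        ]
        return "\n".join(lines)


class ExponentialDecayModel:
    """Least-squares single-exponential decay model for a (t, y) series.

    The initial guess follows the shape of the data: B0 is the mean of the
    last 10% of y, A0 = y(0) - B0, and tau0 the first time y - B0 drops
    below A0/e (falling back to a third of the time range).
    """

    def __init__(self, t: np.ndarray, y: np.ndarray):
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be equal-length 1D arrays")
        if self.t.size < 4:
            raise ValueError("need at least 4 points to fit 3 parameters")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.ptp(self.y) == 0.0:
            raise ValueError("y is constant; exponential fit is degenerate")

    def initial_guess(self) -> np.ndarray:
        t, y = self.t, self.y
        tail = max(1, int(round(0.1 * y.size)))
        B0 = float(y[-tail:].mean())
        A0 = float(y[0] - B0)
        tau0 = None
        if A0 != 0.0:
            # first crossing of the 1/e level of the decaying part
            below = np.flatnonzero((y - B0) / A0 < np.exp(-1.0))
            if below.size and below[0] > 0:
                tau0 = float(t[below[0]] - t[0])
        if tau0 is None or tau0 <= 0:
            tau0 = float(np.ptp(t) / 3.0)
        if A0 == 0.0:
            A0 = float(y[0] - y[-1]) or float(np.ptp(y))
        return np.array([A0, tau0, B0])

    @staticmethod
    def _residuals(p: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
        A, tau, B = p
        return A * np.exp(-t / tau) + B - y

    def fit(self, xtol: float = 1e-10) -> ExpFitResults:
        p0 = self.initial_guess()
        rss0 = float((self._residuals(p0, self.t, self.y) ** 2).sum())
        sol = least_squares(
            self._residuals, p0, args=(self.t, self.y),
            bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=xtol, ftol=1e-15, gtol=1e-15, max_nfev=10_000,
        )
        rss = float((sol.fun ** 2).sum())
        if rss > rss0:  # never report an iterate worse than the start
            return ExpFitResults(A=float(p0[0]), tau=float(p0[1]), B=float(p0[2]),
                                 rss=rss0, converged=False, n_obs=self.t.size,
                                 nfev=int(sol.nfev))
        A, tau, B = sol.x
        return ExpFitResults(A=float(A), tau=float(tau), B=float(B), rss=rss,
                             converged=bool(sol.success), n_obs=self.t.size,
                             nfev=int(sol.nfev))


def fit_exponential(series: QbSeries | tuple[np.ndarray, np.ndarray],
                    time_unit_ps: float = 1000.0) -> ExpFitResults:
    """Fit A exp(-t/tau) + B to a QbSeries (t converted ps -> ns) or a raw
    (t, y) pair taken as-is (tau in the unit of t)."""
    if isinstance(series, QbSeries):
        t = series.times / time_unit_ps
        y = series.qb
    else:
        t, y = series
    return ExponentialDecayModel(t, y).fit()
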