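"""2D pseudo-free-energy surfaces from paired descriptor series.

Two order parameters (canonically RMSD and Rg) are histogrammed on an
equal-width 8x8 grid spanning each axis's data range.  The normalized bin
probability P is inverted to a free-energy-like surface G = -ln(P / P_max)
in kT units: only relative depths are meaningful, the occupied minimum is
exactly 0 and empty bins carry +inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DescriptorSeries

__all__ = ["Landscape2D", "BasinSummary", "energy_landscape", "basin_summary"]


class DegenerateAxisError(ValueError):
    """An axis has zero variance; equal-width binning is undefined."""


@dataclass
class Landscape2D:
    x_edges: np.ndarray  # (nx+1,)
    y_edges: np.ndarray  # (ny+1,)
    P: np.ndarray        # (nx, ny), sums to 1
    G: np.ndarray        # (nx, ny), kT units, +inf in empty bins
    x_label: str = "x"
    y_label: str = "y"

    @property
    def n_cells(self) -> int:
        return int(self.P.size)


@dataclass
class BasinSummary:
    """Edge intervals of the minimum-G cell(s) and their probability mass."""

    x_ranges: list[tuple[float, float]]
    y_ranges: list[tuple[float, float]]
    p_basin: list[float]


def energy_landscape(x: DescriptorSeries | np.ndarray, y: DescriptorSeries | np.ndarray,
                     bins_per_axis: int = 8) -> Landscape2D:
    """Histogram two equal-length descriptor series into a Landscape2D.

    Bin edges are equal-width over [min, max] of each axis (per-trajectory
    ranges, matching per-system landscape panels).
    """
    x_label = getattr(x, "label", "x") or "x"
    y_label = getattr(y, "label", "y") or "y"
    xv = np.asarray(getattr(x, "values", x), dtype=float)
    yv = np.asarray(getattr(y, "values", y), dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1D series")
    if bins_per_axis < 2:
        raise ValueError("bins_per_axis must be >= 2")
    if xv.size < bins_per_axis:
        raise ValueError(f"need at least {bins_per_axis} samples, got {xv.size}")
    for name, v in (("x", xv), ("y", yv)):
        if np.ptp(v) == 0.0:
            raise DegenerateAxisError(f"{name} axis has zero variance")
    counts, x_edges, y_edges = np.histogram2d(xv, yv, bins=bins_per_axis)
    P = counts / counts.sum()
    with np.errstate(divide="ignore"):
        G = -np.log(P / P.max())
    G[P == 0] = np.inf
    return Landscape2D(x_edges=x_edges, y_edges=y_edges, P=P, G=G,
                       x_label=x_label, y_label=y_label)


def basin_summary(ls: Landscape2D) -> BasinSummary:
    """The minimum-G (maximum-P) cell; all cells are listed on ties."""
    pmax = ls.P.max()
    xs, ys = np.nonzero(ls.P == pmax)
    return BasinSummary(
        x_ranges=[(float(ls.x_edges[i]), float(ls.x_edges[i + 1])) for i in xs],
        y_ranges=[(float(ls.y_edges[j]), float(ls.y_edges[j + 1])) for j in ys],
        p_basin=[float(ls.P[i, j]) for i, j in zip(xs, ys)],
    )
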