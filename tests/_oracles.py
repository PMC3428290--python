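"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths under test: superposition is
minimized by exhaustive search over a hierarchically refined Euler-angle
grid (the optimal translation is centroid alignment in closed form), and
occupancies are recounted frame by frame with plain Python loops.
"""

import numpy as np
from scipy.spatial.transform import Rotation


def brute_force_superposed_rmsd(mobile, reference, levels=7, coarse=24, refine=11):
    """Minimal RMSD over SO(3) x R^3 by hierarchical exhaustive grid search.

    Translations are eliminated exactly by centering both sets; rotations are
    scanned on an Euler-angle grid that is refined ``levels`` times around
    the running best, down to ~1e-4 rad resolution.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    am = mobile - mobile.mean(axis=0)
    ar = reference - reference.mean(axis=0)
    n = len(am)

    def rmsd_for(angles):
        Rm = Rotation.from_euler("zyz", angles).as_matrix()  # (k, 3, 3)
        rotated = np.einsum("kij,aj->kai", Rm, am)
        return np.sqrt(((rotated - ar) ** 2).sum(axis=(1, 2)) / n)

    center = np.array([0.0, np.pi / 2, 0.0])     # alpha, beta, gamma (zyz)
    spans = np.array([np.pi, np.pi / 2, np.pi])  # half-widths: beta in [0, pi]
    best_angles, best_val = center, np.inf
    for level in range(levels):
        steps = coarse if level == 0 else refine
        axes = [np.linspace(c - s, c + s, steps) for c, s in zip(center, spans)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = rmsd_for(grid)
        k = int(np.argmin(vals))
        if vals[k] < best_val:
            best_val, best_angles = float(vals[k]), grid[k]
        center = best_angles
        spans = spans * (2.0 / (steps - 1))  # keep one coarse cell each side
    return best_val


def recount_population(distances, cutoff, strict=True):
    """Per-frame recount of a distance-criterion occupancy with a plain loop."""
    hits = 0
    for d in distances:
        if (d < cutoff) if strict else (d <= cutoff):
            hits += 1
    return hits / len(distances)
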