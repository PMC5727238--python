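"""Independent brute-force oracles for the constrained decomposition.

These deliberately avoid the package's active-set solver: both constrained
problems are solved by dense grid search over the fraction space — a coarse
exhaustive sweep followed by local exhaustive sweeps at step 1e-3 and then
1e-4 (valid because both objectives are strictly convex, so the coarse argmin
brackets the continuous one). The soft-mode oracle exploits that the air
basis has zero attenuation in the synthetic calibrations, so for fixed
(F_stain, F_pmma) the optimal F_air is max(0, 1 - F_stain - F_pmma) in
closed form and the search is over two dimensions.
"""

import numpy as np


def _grid2(center, half, step):
    ax = np.arange(-half, half + step / 2, step)
    d1, d2 = np.meshgrid(ax, ax, indexing="ij")
    pts = np.stack([d1.ravel(), d2.ravel()], axis=1) + center
    return np.clip(pts, 0.0, None)


def grid_soft_oracle(calset, b, w=1.0, span=1.6):
    """Grid-search argmin of the soft three-material objective for one voxel.

    ``b = (mu_LE, mu_HE)``. Requires the air basis attenuation to be zero
    (true for the synthetic calibrations), which reduces the search to the
    (F_stain, F_pmma) plane with the closure penalty
    ``w^2 * max(0, F_stain + F_pmma - 1)^2``.
    """
    assert calset.le["air"] == 0.0 and calset.he["air"] == 0.0
    a2 = calset.matrix2()
    b = np.asarray(b, dtype=float)

    def best_on(points):
        resid = points @ a2.T - b
        closure = np.maximum(0.0, points.sum(axis=1) - 1.0)
        obj = np.einsum("ij,ij->i", resid, resid) + (w * closure) ** 2
        return points[np.argmin(obj)]

    ax = np.arange(0.0, span + 1e-12, 0.005)
    g1, g2 = np.meshgrid(ax, ax, indexing="ij")
    center = best_on(np.stack([g1.ravel(), g2.ravel()], axis=1))
    center = best_on(_grid2(center, 0.12, 0.001))
    f12 = best_on(_grid2(center, 0.003, 0.0001))
    f_air = max(0.0, 1.0 - f12.sum())
    return np.array([f12[0], f12[1], f_air])


def simplex_grid_points(step=1e-3):
    """All (f1, f2, f3) on the unit simplex with f1, f2 on a `step` lattice."""
    n = int(round(1.0 / step))
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    keep = i + j <= n
    f1 = i[keep] * step
    f2 = j[keep] * step
    return np.stack([f1, f2, 1.0 - f1 - f2], axis=1)


def grid_hard_oracle(a, b, points):
    """Grid-search argmin over the simplex: exhaustive 1e-3 sweep (the
    ``points`` lattice) followed by a local exhaustive 1e-4 sweep."""
    b = np.asarray(b, dtype=float)

    def best_on(pts):
        proj = pts @ a.T
        r2 = np.einsum("ij,ij->i", proj, proj) - 2.0 * proj @ b
        return pts[np.argmin(r2)]

    coarse = best_on(points)
    local = _grid2(coarse[:2], 0.003, 0.0001)
    f3 = 1.0 - local.sum(axis=1)
    fine = np.concatenate([local, f3[:, None]], axis=1)
    fine = fine[fine[:, 2] >= -1e-12]
    fine[:, 2] = np.clip(fine[:, 2], 0.0, None)
    return best_on(fine)
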