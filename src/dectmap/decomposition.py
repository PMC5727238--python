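"""Voxel-wise constrained material decomposition — the core computation.

Each voxel's pair of effective attenuation coefficients (mu_LE, mu_HE) is
expressed as a non-negative mixture of calibration materials:

    mu_LE = mu_stain,LE * F_stain + mu_pmma,LE * F_pmma (+ mu_air,LE * F_air)
    mu_HE = mu_stain,HE * F_stain + mu_pmma,HE * F_pmma (+ mu_air,HE * F_air)

Three modes are offered:

``two_material``
    Non-negative least squares on the 2x2 system in (F_stain, F_pmma).
``three_material_soft`` (default)
    Adds air as a third material and the closure row
    ``1 = F_stain + F_pmma + F_air`` as a *weighted equation* (weight ``w``,
    default 1). Fractions may individually exceed 1 and their sum may deviate
    from 1 — which is what lets strongly staining tissue report fractions
    around 1.3 of the calibration solution.
``three_material_hard``
    Minimizes the attenuation misfit over the probability simplex (sum
    exactly 1, all fractions >= 0).

The solver enumerates active sets: for a convex non-negative least-squares
problem in at most three unknowns, the optimum restricted to its support is
the unconstrained (or equality-constrained) least-squares solution on that
support, so checking every support and keeping the best feasible candidate is
exact. With the system matrix shared by all voxels the per-support solution
operators are precomputed once and applied to all voxels at once, making the
result independent of voxel processing order by construction.

Negative attenuation inputs (scattering artifacts) are accepted, never
clipped; non-negativity applies to the fractions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .calibration import CalibrationSet
from .volume import AttenuationVolume, as_mask

MODES = ("two_material", "three_material_soft", "three_material_hard")
_MODE_ALIASES = {"two": "two_material", "soft": "three_material_soft", "hard": "three_material_hard"}

_FEAS_TOL = 1e-9


def _canonical_mode(mode: str) -> str:
    mode = _MODE_ALIASES.get(mode, mode)
    if mode not in MODES:
        raise ValueError(f"unknown decomposition mode {mode!r}; choose from {MODES}")
    return mode


@dataclass
class FractionMap:
    """Per-voxel basis-material fractions and attenuation-row residuals.

    Arrays are voxel-congruent with the decomposed volumes; voxels outside
    the requested mask are not computed and hold NaN, with ``valid`` False.
    ``residual`` is the 2-norm misfit of the two attenuation equations
    (mm^-1); the closure row never contributes to it.
    """

    f_stain: np.ndarray
    f_pmma: np.ndarray
    f_air: np.ndarray
    residual: np.ndarray
    valid: np.ndarray
    mode: str
    meta: dict = field(default_factory=dict)

    @property
    def f_total(self) -> np.ndarray:
        return self.f_stain + self.f_pmma + self.f_air


def _nnls_supports(a: np.ndarray) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Pseudo-inverse solution operators for every support of an NNLS problem."""
    k = a.shape[1]
    ops = []
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            ops.append((support, np.linalg.pinv(a[:, support])))
    return ops


def _nnls_batch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact batched NNLS: min ||a x - b_i||, x >= 0, for every row b_i."""
    n, k = b.shape[0], a.shape[1]
    best_x = np.zeros((n, k))
    best_r2 = np.einsum("ij,ij->i", b, b)  # empty support: x = 0
    for support, pinv in _nnls_supports(a):
        x_s = b @ pinv.T
        feasible = np.all(x_s >= -_FEAS_TOL, axis=1)
        resid = x_s @ a[:, support].T - b
        r2 = np.einsum("ij,ij->i", resid, resid)
        better = feasible & (r2 < best_r2 - 1e-15)
        if np.any(better):
            best_r2[better] = r2[better]
            best_x[better] = 0.0
            cols = np.asarray(support)
            best_x[np.ix_(better, cols)] = x_s[better]
    return np.clip(best_x, 0.0, None), best_r2


def _simplex_ops(a: np.ndarray) -> list[tuple[tuple[int, ...], np.ndarray, np.ndarray]]:
    """Affine solution operators x = G b + h for each face of the simplex."""
    k = a.shape[1]
    ops = []
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            a_s = a[:, support]
            m = np.zeros((size + 1, size + 1))
            m[:size, :size] = 2.0 * a_s.T @ a_s
            m[:size, size] = 1.0
            m[size, :size] = 1.0
            try:
                m_inv = np.linalg.inv(m)
            except np.linalg.LinAlgError:
                continue
            g = m_inv[:size, :size] @ (2.0 * a_s.T)
            h = m_inv[:size, size]
            ops.append((support, g, h))
    return ops


def _simplex_lsq_batch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched min ||a x - b_i|| s.t. x >= 0 and sum(x) = 1 (face enumeration)."""
    n, k = b.shape[0], a.shape[1]
    best_x = np.full((n, k), np.nan)
    best_r2 = np.full(n, np.inf)
    for support, g, h in _simplex_ops(a):
        x_s = b @ g.T + h
        feasible = np.all(x_s >= -_FEAS_TOL, axis=1)
        resid = x_s @ a[:, support].T - b
        r2 = np.einsum("ij,ij->i", resid, resid)
        better = feasible & (r2 < best_r2 - 1e-15)
        if np.any(better):
            best_r2[better] = r2[better]
            best_x[better] = 0.0
            cols = np.asarray(support)
            best_x[np.ix_(better, cols)] = x_s[better]
    return np.clip(best_x, 0.0, None), best_r2


def decompose_values(
    mu_le: np.ndarray,
    mu_he: np.ndarray,
    calset: CalibrationSet,
    mode: str = "three_material_soft",
    sum_weight: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose flat arrays of attenuation pairs.

    Returns ``(fractions, residual)`` where ``fractions`` has one column per
    material — (stain, pmma) in two-material mode, (stain, pmma, air)
    otherwise — and ``residual`` is the 2-norm misfit of the two attenuation
    rows per voxel.
    """
    mode = _canonical_mode(mode)
    calset.validate()
    mu_le = np.asarray(mu_le, dtype=float).ravel()
    mu_he = np.asarray(mu_he, dtype=float).ravel()
    if mu_le.shape != mu_he.shape:
        raise ValueError("LE and HE value arrays differ in length")
    if not (np.all(np.isfinite(mu_le)) and np.all(np.isfinite(mu_he))):
        raise ValueError("attenuation inputs must be finite")
    b2 = np.stack([mu_le, mu_he], axis=1)

    if mode == "two_material":
        a2 = calset.matrix2()
        x, _ = _nnls_batch(a2, b2)
        resid = x @ a2.T - b2
    elif mode == "three_material_soft":
        if sum_weight <= 0:
            raise ValueError(f"sum_weight must be positive, got {sum_weight}")
        a3 = np.vstack([calset.matrix3(), sum_weight * np.ones(3)])
        b3 = np.concatenate([b2, np.full((b2.shape[0], 1), sum_weight)], axis=1)
        x, _ = _nnls_batch(a3, b3)
        resid = x @ calset.matrix3().T - b2
    else:  # three_material_hard
        x, _ = _simplex_lsq_batch(calset.matrix3(), b2)
        resid = x @ calset.matrix3().T - b2
    residual = np.linalg.norm(resid, axis=1)
    return x, residual


def solve_voxel(
    mu_le: float,
    mu_he: float,
    calset: CalibrationSet,
    mode: str = "three_material_soft",
    sum_weight: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Decompose a single voxel; see :func:`decompose_values`."""
    x, residual = decompose_values(
        np.atleast_1d(mu_le), np.atleast_1d(mu_he), calset, mode, sum_weight
    )
    return x[0], float(residual[0])


def decompose_volume(
    vol_le: AttenuationVolume,
    vol_he: AttenuationVolume,
    calset: CalibrationSet,
    mode: str = "three_material_soft",
    mask: np.ndarray | None = None,
    sum_weight: float = 1.0,
    chunk: int = 1 << 18,
) -> FractionMap:
    """Decompose a registered dual-energy volume pair into fraction maps.

    Voxels outside ``mask`` (if given) are left not-computed (NaN with
    ``valid`` False). The volumes must already be registered and congruent.
    """
    mode = _canonical_mode(mode)
    vol_le.check_congruent(vol_he)
    shape = vol_le.data.shape
    valid = (
        np.ones(shape, dtype=bool) if mask is None else as_mask(mask, like=vol_le)
    )
    flat_le = vol_le.data[valid]
    flat_he = vol_he.data[valid]

    n = flat_le.size
    k = 2 if mode == "two_material" else 3
    fractions = np.empty((n, k))
    residual = np.empty(n)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        fractions[sl], residual[sl] = decompose_values(
            flat_le[sl], flat_he[sl], calset, mode, sum_weight
        )

    def scatter(col: np.ndarray | None) -> np.ndarray:
        out = np.full(shape, np.nan)
        out[valid] = col if col is not None else 0.0
        return out

    fmap = FractionMap(
        f_stain=scatter(fractions[:, 0]),
        f_pmma=scatter(fractions[:, 1]),
        f_air=scatter(fractions[:, 2] if k == 3 else None),
        residual=scatter(residual),
        valid=valid,
        mode=mode,
        meta={
            "sum_weight": sum_weight if mode == "three_material_soft" else None,
            "calibration": {"le": dict(calset.le), "he": dict(calset.he)},
            "kvp": calset.kvp,
            "computed_voxels": int(valid.sum()),
        },
    )
    return fmap
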