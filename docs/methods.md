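# Methods

## The measurement model

A reconstructed micro-CT volume acquired with one broad-band spectrum
assigns each voxel an effective polychromatic linear attenuation
coefficient µ (mm⁻¹). For a sample containing at most three materials with
distinct spectral responses — staining solution, soft tissue (approximated
by PMMA, the calibration surrogate), and air — two acquisitions with
sufficiently different spectra determine the per-voxel material fractions.
The basis coefficients µ_m,LE and µ_m,HE are measured, not modelled: they
are arithmetic means of the reconstructed calibration phantom over each
material's region (a trimmed mean is available for artifact-laden regions).
Air coefficients come from phantom-free regions and are near zero.

Whether the system is solvable in practice is an angular question: the
stain and PMMA column vectors of the 2×2 system must not be collinear
across the two spectra. `conditioning` reports the 2-norm condition number
of the column-normalized matrix (1 = orthogonal responses, ∞ = no
separation) with a warn threshold of 20, chosen empirically as the point
where noise amplification in the fractions becomes comparable to the
signal; a singular system is rejected outright before any voxel is
processed.

## Decomposition modes and the closure row

Writing A for the 2×3 attenuation matrix and b = (µ_LE, µ_HE) for a voxel:

* **two_material** — non-negative least squares (NNLS) on the 2×2
  stain/PMMA block.
* **three_material_soft** (default) — NNLS on the stacked system
  [A; w·1ᵀ] f = [b; w]: the closure row "fractions sum to one" enters as a
  *weighted equation* with weight w (default 1, configurable). Fractions may
  individually exceed 1 and the sum may deviate from 1.
* **three_material_hard** — least squares over the probability simplex
  (sum exactly 1, enforced to machine precision through the KKT system).

The soft default is deliberate. Strongly staining tissue concentrates the
agent beyond the calibration bath concentration, and the observable
signature — voxels reporting ≈1.3× the calibration solution — only exists
if the unit-sum closure can bend. Hard mode is retained for samples known
to be closed mixtures. The reported per-voxel residual is always the
2-norm misfit of the two attenuation rows alone, so residuals are
comparable across modes; note that the soft optimum trades attenuation
misfit against closure misfit, so its attenuation residual can exceed the
two-material one on voxels whose true fractions sum beyond 1 (the joint
soft objective is still never worse than that of the embedded two-material
solution, which the test suite checks).

The solver enumerates active sets. For a convex NNLS problem in ≤ 3
unknowns the optimum restricted to its support is the unconstrained (or
equality-constrained) least-squares solution on that support, so evaluating
every support and keeping the best feasible candidate is exact — no
iteration, no tolerance tuning. Because the system matrix is shared by all
voxels, the per-support solution operators are precomputed once and applied
to whole volumes as matrix products; results are independent of voxel
processing order by construction, and ties between supports resolve to a
fixed enumeration order. Negative attenuation inputs (scattering
artifacts) are accepted unclipped; non-negativity applies to fractions
only. Voxels outside the analysis mask are NaN with an accompanying
boolean validity mask.

The independent check on this solver is a dense grid search
(`tests/_oracles.py`): an exhaustive coarse sweep of the fraction space
followed by local exhaustive sweeps at steps 10⁻³ and 10⁻⁴ — valid because
both objectives are strictly convex. The soft-mode oracle exploits the zero
air attenuation of the synthetic calibrations to reduce the search to two
dimensions with closed-form air. SciPy's NNLS serves as a second,
sharper cross-check.

## Registration, filtering, masks

The two energy volumes are aligned post-reconstruction with a
content-moving rigid transform: translation in voxels plus intrinsic
z–y–x Euler angles (degrees) about the volume center, arrays indexed
(z, y, x), voxel centers at integer coordinates. The similarity metric is
normalized cross-correlation, since the two spectra scale each material
differently and make sum-of-squares misleading; optimization is a
phase-correlation translation initialisation followed by Powell refinement
of all six parameters (bounds ±15 voxels, ±10°, xtol 10⁻³). Resampling is
trilinear with a configurable fill value (air estimate by default); pure
integer translations short-circuit to exact lattice shifts. A result whose
final correlation is below 0.5 or worse than the starting point (beyond a
0.01 interpolation allowance) is flagged not-converged with diagnostics
rather than silently returned. On the 64³ test phantoms a programmed
(3.5, −2.25, 1.0)-voxel shift with a 2° rotation is recovered to ≈0.01
voxel and ≈0.1°.

Median filtering (cubic neighborhood, reflecting edges) is the standard
denoising step before decomposition; radius 1 is the pipeline default.
Sample masks drawn on sparse slices are propagated by signed-distance
interpolation: annotated slices are reproduced exactly, intermediate slices
threshold the linearly blended signed Euclidean distance transforms of the
bracketing annotations, and the nearest annotation extends beyond the
annotated range.

## Volumetry and histograms

Sample volume = (count of above-threshold voxels after container removal,
with enclosed cavities filled) × (voxel size)³. Cavity filling is a 3D
flood fill from all grid borders: any sub-threshold region not reachable
from the border is an internal chamber and counts toward the sample volume.
The threshold is explicit configuration; an Otsu two-class threshold is
offered as an opt-in default for synthetic demonstrations, since a
threshold appropriate for real reconstructions depends on the acquisition.

2D correlation histograms count voxels by their (µ_LE, µ_HE) pair; default
edges span the 0.1–99.9 percentile range per channel in 256 bins, and
out-of-range values are clipped into the edge bins so the total count
always equals the mask cardinality.

## The synthetic phantoms

Real stained-organ scans are not redistributable, so validation runs on
generated stand-ins whose truth is known exactly.

* **Calibration phantom**: PMMA rod and stain tube (cylinders along z) in
  air, each voxel carrying its basis coefficient plus noise.
* **Organ phantom**: an ellipsoidal organ (default 64³ grid, 12 µm voxels,
  semi-axes 26/22/20 voxels) inside a PMMA-walled tube, split by a plane
  into a "heart" and a "lung" compartment, both reaching the surface as in
  an organ pair bathed in staining solution. The stain fraction at depth d
  below the organ surface after staining time t is the half-space diffusion
  profile min(F_max, F_surface · erfc(d / 2√(Dt))), evaluated on the
  discrete Euclidean distance transform of the rasterized organ. Defaults:
  heart D = 1.0 voxel²/min, F_surface = 1.5, F_max = 1.3 (a tissue that
  concentrates the agent to 1.3× the bath); lung D = 0.35, F_surface =
  F_max = 1.0. Unstained tissue sits on the PMMA basis, so noise-free
  phantoms lie exactly in the decomposition's span and the mixture identity
  holds to machine precision.
* **Perturbations**: i.i.d. Gaussian reconstruction-domain noise (a proxy
  for the projection-domain noise chain, which is out of scope together
  with reconstruction itself); a multiplicative radial cupping bias
  µ·(1 − β(1 − r/R)) emulating beam hardening; rigid misalignment of the
  high-energy volume; and volume shrinkage applied as an isotropic linear
  scale s^(1/3) of the organ geometry about its centroid, so the enclosed
  volume scales by the factor s (default staining scenario: s = 0.8 at the
  first round, mimicking the dehydration shrinkage of ethanol-based
  staining, then 1.0).

The synthetic calibration presets (I2E-like: stain 3.2/1.1, PMMA 0.7/0.5,
air 0/0 mm⁻¹ at 40.2/70.1 kVp; Gadovist-like: 2.1/0.75, 0.55/0.45 at
60.2/140.0 kVp) are package defaults chosen once for physical
plausibility — strong low-energy photoelectric uptake of the heavy-element
stain, weak spectral dependence of PMMA — and good conditioning (≈6.9).
They are labelled synthetic in their provenance metadata; measured
coefficients from a real calibration scan replace them via
`estimate_basis`.

What the phantoms do **not** emulate: polychromatic spectrum physics and
beam-hardening beyond the parametric cupping term, scatter, partial-volume
blur at material interfaces, anisotropic tissue diffusivity, and real organ
morphology. Passing tests therefore demonstrate the correctness of the
numerics and the pipeline plumbing under the stated noise model, not the
biological accuracy of any uptake value on real scans.

## Problem sizes and numerical choices

Validation experiments run on 64³ volumes (tests use 48³ where geometry
suffices), sizes at which every stage's behaviour — boundary effects,
conditioning, noise scaling — is already representative. Feasibility
tolerance of the active-set solver is 10⁻⁹ with final clipping of
sub-tolerance negatives to zero; hard-mode sums are exact to ~10⁻¹⁵.
Degenerate registration inputs (structureless volumes) are flagged via the
correlation threshold. The erfc profile at t = 0 is defined as 0 at
positive depth and F_surface at depth 0; rasterized organ voxels always
have depth ≥ 1, so an unstained (t = 0) phantom is exactly PMMA-valued
inside the organ.

## Known limitations

* Registration assumes small rotations (≤ 10° by default) and overlapping
  content; it is rigid only.
* The soft-mode closure weight w mixes units (mm⁻¹ rows against a
  dimensionless row); with the default w = 1 the closure influence depends
  on the magnitude of the basis coefficients. This mirrors the plain
  stacked-system formulation; rescale w for calibrations far from O(1) mm⁻¹.
* Volumetry is threshold-sensitive by design (the threshold is part of the
  protocol) and suited to comparisons across time points rather than
  absolute sizes.
* Fraction maps are only as quantitative as the calibration: drift between
  the phantom scan and the sample scan propagates directly into F values.
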