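# dectmap

Quantifying contrast-agent uptake in chemically stained soft tissue with
**dual-energy micro-CT (DECT)**.

Staining *ex-vivo* organs with X-ray-dense agents — elemental iodine in
ethanol (I2E) or the clinical gadolinium agent Gadovist (Gadobutrol,
1.0 mmol/mL ≙ 604.72 mg/mL) — makes soft-tissue structure visible in
absorption micro-CT. A single scan, however, cannot separate "more stain"
from "denser tissue". Scanning the same sample with two X-ray spectra (low-
and high-energy) does: each voxel's pair of effective polychromatic
attenuation coefficients (µ_LE, µ_HE), in mm⁻¹, is expressed as a mixture of
calibration materials measured under identical settings — the staining
solution, PMMA as soft-tissue equivalent, and air:

```
µ_LE = µ_stain,LE · F_stain + µ_PMMA,LE · F_PMMA + µ_air,LE · F_air
µ_HE = µ_stain,HE · F_stain + µ_PMMA,HE · F_PMMA + µ_air,HE · F_air
  1  =             F_stain +            F_PMMA +            F_air
```

solved voxel-wise by non-negative least squares. The fractions F are
expressed relative to the calibration staining solution; tissue that
concentrates the agent beyond the bath concentration legitimately reports
F_stain > 1, which is why the default solver mode treats the closure row as
a weighted equation rather than a hard constraint. The package covers the
full analysis for sequential staining experiments:

* **Calibration** (`dectmap.calibration`) — basis coefficients as region
  means over a PMMA-rod/stain-tube phantom scan, with an angular
  conditioning check that the two spectra actually separate the materials.
* **Preprocessing** (`dectmap.preprocess`) — rigid registration of the two
  energy volumes (normalized cross-correlation, translation + rotation),
  median filtering, and sample masks interpolated from sparse hand-drawn
  slice annotations.
* **Decomposition** (`dectmap.decomposition`) — exact vectorized active-set
  NNLS in three modes (two-material, soft three-material, simplex-hard).
* **Quantification** (`dectmap.quantify`) — sample volume by voxel counting
  (enclosed cavities included), relative-volume and mean-attenuation
  time-courses, 2D low/high-energy correlation histograms, per-tissue
  uptake summaries.
* **Synthetic phantoms** (`dectmap.phantoms`) — dual-energy volume pairs
  with exact ground truth: a calibration phantom and an organ-like sample
  ("heart" and "lung" compartments) whose stain fraction follows a
  diffusion-from-the-surface profile, with programmable shrinkage, noise,
  cupping bias and misalignment. Every pipeline stage is validated against
  these generated truths.

## Worked example

Simulate a stained organ at 90 min, decompose it, and summarise uptake per
tissue:

```python
import numpy as np
from dectmap import (OrganPhantomSpec, NoiseSpec, synthetic_calibration_i2e,
                     make_organ_phantom, median_filter, decompose_volume,
                     uptake_summary)

calset = synthetic_calibration_i2e()
spec = OrganPhantomSpec()                      # 64^3 heart+lung phantom
le, he, truth = make_organ_phantom(spec, calset, t=90.0,
                                   noise=NoiseSpec(sigma=0.05, seed=0))
le, he = median_filter(le, 1), median_filter(he, 1)
fmap = decompose_volume(le, he, calset, "three_material_soft",
                        mask=truth.organ_mask)
summary = uptake_summary(fmap, truth.compartment_masks, t=90.0)
print(summary.to_frame().to_string(index=False))
err = (fmap.f_stain - truth.f_stain)[truth.organ_mask]
print(f"RMSE vs ground truth: {np.sqrt((err**2).mean()):.4f}")
```

```
label  time_min  mean_f_stain  max_f_stain  voxel_count
heart      90.0      1.044776     1.281127        16864
 lung      90.0      0.499980     0.921351        31048
RMSE vs ground truth: 0.0422
```

The heart compartment (higher stain diffusivity, concentrating the agent to
1.3× the bath) reports roughly twice the lung's mean stain fraction, with a
peak close to the programmed 1.3; the per-voxel recovery error under 5%
scan noise is ≈ 0.04 fraction units.

The same stages are scriptable from the shell via the `dectmap` CLI
(`simulate`, `calibrate`, `register`, `decompose`, `quantify`, `run`); the
`run` subcommand chains them over a YAML config and writes fraction maps,
CSV time-courses and a reproducibility manifest.

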