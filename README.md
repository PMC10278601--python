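# henlepol

Quantitative analysis of **Henle's fiber layer (HFL)** with
polarization-sensitive optical coherence tomography (PS-OCT), built and
validated entirely on a synthetic PS-OCT data generator with known ground
truth.

Henle fibers are the photoreceptor axons that radiate outward from the
fovea.  They backscatter too weakly to be seen in ordinary OCT intensity
images, but as fibrous tissue they are form-birefringent: PS-OCT measures
the retardation δ they introduce and the optic-axis orientation θ that
tracks the fiber direction.  Because the fibers run radially, θ measured
on a circle around the fovea increases linearly with the azimuth angle φ —
a fingerprint that can be detected statistically even when the signal is
weak.  This package implements that detection pipeline for researchers in
retinal imaging and ophthalmic optics:

* **Stokes-vector polarization core** — retardation δ = ½·arccos(⟨Q/I⟩_N)
  and axis θ from en-face Stokes maps, bias-free Stokes-component
  averaging, DOPU, and a Poincaré-sphere retarder model;
* **anterior birefringence compensation** — the cornea + retinal nerve
  fiber layer act as a retarder in front of HFL; their effect is measured
  at a reference surface and inverted per A-line;
* **the mean-deviation (MD) statistic** — axis orientation is embedded on
  the unit circle as Z = e^{i2θ} (axial data, half-turn periodic), averaged
  in 360 one-degree azimuthal segments per 1°-wide annulus, and compared
  with the ideal radial pattern by the mean L1 distance
  MD = mean(|ΔRe Z| + |ΔIm Z|).  A perfect radial pattern gives MD = 0; a
  completely random axis map gives the noise floor 4/π ≈ 1.27 (≈1.3).
  HFL is considered present while MD < 0.65, half the noise floor;
* **a four-step correction pipeline** — global axis-rotation anchor,
  iterative fovea-center refinement (31×31 px exhaustive MD minimization),
  a ±5° grid search over compensation offsets, and a final center
  refinement;
* **HFL lateral extension** — the eccentricity where the MD-vs-annulus
  curve crosses 0.65, interpolated between annulus mid-radii;
* **circumferential retardation metrics** — the "donut" profile (peak ≈ 9°
  near 2° eccentricity), its peak, peak eccentricity, AUC over 1–8°, and
  per-annulus means;
* **cohort statistics** — Student's t-tests, box-plot summaries with the
  1.5·IQR rule, SNR-vs-extension regression, and test–retest repeatability;
* **a synthetic PS-OCT generator** — en-face Stokes maps on the 28°×21°
  (1024×250 px) field with a configurable fovea position, a raised-cosine
  donut retardation profile, nasal–temporal asymmetry, an anterior
  retarder, Gaussian Stokes noise at a configurable SNR, and small layered
  volumes (IS/OS band, depolarizing RPE, depth-decaying noise floor) for
  the volume-level operators.

## Worked example

```python
import numpy as np
from henlepol import SceneGeometry, full_correction, hfl_extension
from henlepol.synthetic import HenleGroundTruth, simulate_subject

geom = SceneGeometry()                       # 28°×21°, 1024×250 px, 860 nm
truth = HenleGroundTruth(
    fovea_center=(520.0, 130.0), hfl_extension=9.0,
    peak_retardation=9.5, peak_eccentricity=2.0, asymmetry_ratio=1.2,
    anterior_retardation=20.0, anterior_axis=35.0,
    snr_db=25.0, rotation_offset=25.0, seed=2)

# reference measured with a systematic (+3°, −2°) error, initial fovea
# guess displaced from the truth — the pipeline must undo both
ds = simulate_subject(truth, geom, reference_perturbation=(3.0, -2.0))
res = full_correction(ds)
p = res.profile
print("rotation:", p.rotation_used)          # -25.0
print("offsets:", p.offsets_used)            # (-3.0, 2.0)
print("MD per annulus:", np.round(p.md, 2))
# [0.12 0.03 0.02 0.01 0.01 0.01 0.01 0.01 0.21 0.79 1.22 1.28 1.26 1.28]
print("extension: %.2f deg" % hfl_extension(p)[0])   # 9.26
```

The recovered rotation (−25°) cancels the injected axis-reference offset,
the offset search recovers the reference error exactly on the 1° grid, the
MD stays near 0 inside the layer, rises through the 0.65 cut-off as the
fiber signal fades, and saturates at the ≈1.27 noise floor outside; the
estimated extension (9.26°) matches the 9° ground truth.  A cohort-level
run is available from the shell:

```sh
henlepol cohort --n-healthy 20 --n-glaucoma 20 --seed 1 --out results/demo
henlepol report --cohort-dir results/demo --out results/figs
```

which writes the per-subject table (`cohort.csv`), the group comparison
(`group_stats.csv`: t-tests on extension, peak retardation, AUC and the
seven per-annulus means, and the SNR–extension regression) and summary
figures.

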