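# Methods

## The measurement model

The package analyses en-face polarization-sensitive OCT (PS-OCT) data of
the macula.  The instrument model is a single circularly polarized input
state; every pixel of an en-face map carries a Stokes vector
(I, Q, U, V).  We work in the measurement frame in which the unperturbed
input state lies along +Q: a linear retarder with single-pass retardation
δ and axis orientation θ then moves the polarization state on the
Poincaré sphere by the angle 2δ about the equatorial axis
(0, cos 2θ, sin 2θ).  In this frame the retrieval formulas are

    δ = ½ · arccos(⟨Q/I⟩_N),     δ ∈ [0°, 90°]
    θ = ½ · atan2(⟨U/I⟩_N, −⟨V/I⟩_N),   θ ∈ [−90°, 90°)

with (⟨Q/I⟩_N, ⟨U/I⟩_N, ⟨V/I⟩_N) the unit-normalized mean Stokes
direction; the conventions are fixed so that applying a retarder and
extracting (δ, θ) round-trips exactly, which is the only property any
downstream computation observes.  All retardations are single-pass-
equivalent degrees; δ/360·λ converts to nm of retardance (9° ↔ 21.5 nm at
λ = 860 nm).

Averaging of polarization data is always performed on Stokes components,
never on retardation values: δ ≥ 0 by construction, so averaging noisy
per-pixel retardations biases the result upward, while the retardation of
the averaged Stokes vector does not (verified by Monte-Carlo in the test
suite).  The one deliberate exception is the circumferential profile:
around a full ring the fiber axis sweeps every orientation, so
ring-averaged transverse Stokes components cancel by symmetry and would
drive the converted retardation toward zero.  There the Stokes-level
averaging is local (9×9 px smoothing) and the circumferential stage
averages the smoothed retardation values.

## The MD statistic

Henle fibers radiate from the fovea, so on a circle about the foveal
center the measured axis orientation θ(φ) rises linearly with azimuth φ.
Axis orientation is axial data — θ and θ + 180° are the same orientation —
so θ is embedded on the unit circle with the doubled angle, Z = e^{i2θ}
(the standard treatment of axial quantities in circular statistics).  The
implementation double-checks this choice against the only self-contained
published number available: for a uniformly random axis map the segment
means of Z vanish and the mean L1 distance to the ideal pattern is
E|cos| + E|sin| = 4/π ≈ 1.27, matching the printed noise floor of ≈1.3,
and the presence cut-off of 0.65 is half that floor.  Without the doubled
angle the segment means of e^{iθ} converge to 2/π instead of zero and the
floor would be ≈0.91, inconsistent with both printed values.

Per annulus (fourteen 1°-wide rings, radii 0–14°, membership computed in
degree space because pixels subtend 28/1024 ≈ 0.027° in x but
21/250 = 0.084° in y), Z is averaged in 360 one-degree azimuthal
segments; azimuth φ = 0 at the upward vertical from the foveal center,
increasing counterclockwise.  The statistic is

    MD = mean over nonempty segments of |Re Z̄_s − Re Z_id(φ_s)| + |Im Z̄_s − Im Z_id(φ_s)|

with the ideal pattern anchored at θ_id(0°) = −90°.  Empty segments are
excluded; an annulus with more than half its segments empty is undefined
(this happens for outer annuli whose ring leaves the 21°-tall field).

## The correction pipeline

Four corrections precede the per-annulus analysis, each minimizing MD in
the 1–2° annulus (where HFL retardation is strongest):

1. **Rotation anchor.**  The instrument measures only a relative axis
   orientation.  The required global rotation is read from the azimuthal
   position of the +90° → −90° wrap of the segment-mean axis, then
   refined over ±3° by MD; if no wrap is discernible, the rotation
   minimizing MD over all 180 integer candidates is used (a global
   rotation c multiplies every segment mean by e^{i2c}, so the sweep
   costs one pass over 360 segment means).
2. **Fovea center.**  Iterated exhaustive search: every pixel of a
   31×31 px window around the current center is tried; the minimum-MD
   pixel becomes the new center, to a fixed point (≤20 iterations; ties
   broken by smallest (|Δy|, |Δx|) displacement).
3. **Compensation offsets.**  Anterior birefringence (cornea + RNFL) is
   compensated per pixel from a reference surface measured anterior to
   HFL; small systematic errors in that reference severely distort the
   pattern.  An 11×11 grid of offsets (dδ, dθ) ∈ [−5°, +5°] in 1° steps
   is searched exhaustively; each candidate is recompensated and scored
   by MD, with the rotation re-fitted per candidate because an axis
   offset also shifts the apparent rotation.  Ties break toward the
   smallest |dδ| + |dθ|, then lexicographically.
4. **Center again**, on the recompensated map.

Two robustness measures proved necessary when the initial fovea guess is
up to ~1.3° off (the injected uncertainty of the coarse first guess):
corrections 1+2 are alternated until the center is a fixed point, because
a rotation estimated at a badly displaced center is unusable and vice
versa; and if the alternation still fails to find a credible pattern
(MD > 0.8, between the 0.65 cut-off and the 1.27 noise floor), a joint
search scores every center candidate by its rotation-minimized MD, which
removes the coupling entirely.  Corrections 3+4 are likewise iterated to
a joint fixed point (≤3 rounds): a center found under a miscompensated
map can be several pixels off and tip the offset argmin to a neighboring
grid point.  With these measures, 50/50 synthetic subjects at 25 dB
recover the injected compensation errors exactly and the fovea center to
<1 px; without them, ~6% fail.

**HFL extension** is the eccentricity where the MD curve, scanned outward
from its minimum annulus, first crosses 0.65, linearly interpolated
between annulus mid-radii (the reported extensions are non-integer, which
implies interpolation).  MD everywhere above the cut-off → extension 0,
flagged `no_pattern`; never above → 14° (field limit), flagged
`beyond_field`.  With repeated acquisitions, the repeat with the lowest
mean MD over 1–8° represents the subject.

## Retardation metrics

The corrected Stokes map is smoothed (9×9 px), converted to retardation,
and averaged circumferentially in 0.25° eccentricity bins (the published
curves are continuous without a stated bin width; 0.25° resolves the
donut peak while keeping ≥1000 px per bin).  Scalar summaries: profile
peak and its eccentricity (healthy template ≈9° near 2°), trapezoid AUC
over [1°, 8°] (undefined if the band has empty bins), and per-annulus
means for the seven 1°-rings 1–2° … 7–8°.

## Cohort statistics

Two-sided Student's t-tests (pooled variance; "Student's t-test" without
qualification is read as equal-variance, Welch available as a flag),
box-plot summaries with linear-interpolation percentiles and the
1.5·IQR outlier rule, OLS regression of measured extension on SNR with
the slope's two-sided p, and test–retest repeatability as the per-subject
sample SD of repeated extensions.  The seven per-annulus comparisons are
reported as raw p-values; a Bonferroni option exists but is off by
default, matching how the per-annulus results are reported.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed once:

* **Geometry**: 28° × 21° field, 1024 × 250 px, 860 nm, 8 mm per 28°.
* **Axis field**: θ(φ) = (φ mod 180°) − 90° + rotation_offset — the exact
  radial pattern plus the unknown instrument rotation (sampled uniformly
  over the half-turn).
* **Retardation field**: a raised-cosine bump in eccentricity — 0 at the
  center, peak_retardation at peak_eccentricity, 0 at hfl_extension,
  compactly supported and smooth.  No functional form for the true
  profile is published; only the anchor points (≈9–11° near 2°,
  extensions 5–12°) are, and those are the sampling ranges.  The
  nasal–temporal asymmetry scales the horizontal axis of the
  eccentricity contours (asymmetry_ratio 1.0–1.3, a "slight" asymmetry).
* **Anterior retarder**: one uniform retarder (5–30° at a uniform axis)
  applied to both the IS/OS and the reference map, standing in for
  cornea + RNFL.  A uniform retarder is a simplification — real corneal
  birefringence varies across the pupil and RNFL birefringence varies
  with field position — so passing tests demonstrate correctness of the
  compensation contract, not robustness to spatially varying anterior
  birefringence.
* **Noise**: independent Gaussian noise per Stokes component with
  σ = I·10^(−snr_db/10) (snr_db is an intensity-ratio in dB, the OCT
  convention; the study population is sampled at 15–32 dB, centered on
  24).  Speckle correlation, axial PSF, eye motion and depolarization are
  not modelled; SNR-dependence results are therefore qualitative.
* **Initial fovea guess**: displaced from the truth by up to ±15 px of
  the full-resolution grid (±0.41° in x, ±1.26° in y), the uncertainty
  budget of a coarse RNFL-based first approximation; expressed in
  degrees so it is resolution-independent.
* **Volumes** (for the volume-level operators): a dim inner-retina band,
  a bright reference plane carrying the anterior-corrupted input state, a
  5-px polarization-preserving IS/OS band, a depolarizing RPE band with
  per-pixel random states, and background noise decaying with depth; the
  IS/OS segmentation line is jittered ±3 px to exercise the refinement.

Cohort defaults place the healthy true extension at 8.8° ± 1.2° and the
glaucoma group at 8.4° ± 1.2° with slightly lower peak retardation —
the direction, not the clinical magnitude, of the reported group
differences; the clinical cohort itself is not reproducible from
published numbers.

## Numerical choices and degenerate inputs

* arccos arguments are clipped to [−1, 1]; the axis is undefined (NaN,
  marked invalid) where the transverse Stokes component vanishes — at
  δ = 0 the fiber orientation is simply not observable, which is why the
  central annulus shows elevated MD.
* DOPU and smoothing kernels are cropped at image borders; no padding is
  invented.
* Brightest-pixel selections break ties toward the shallower depth;
  grid searches break ties by the smallest displacement/offset, then
  lexicographically — all outputs are bit-reproducible for a fixed seed.
* A constant B-scan (σ_I = 0) degrades the noise threshold to the mean
  with a logged warning; an all-invalid map leaves the rotation at 0°
  with a warning rather than failing.
* Problem sizes in the test suite: the full 1024×250 grid wherever a
  published number is checked (noise floor, parameter recovery over 50
  subjects); a half-resolution 512×128 grid for cohort-level sweeps,
  where per-segment pixel counts remain ≥2 in the 1–2° annulus and the
  MD statistic behaves identically.

## Known limitations

* The generator begins at the Stokes/intensity level; raw spectral-domain
  reconstruction (spectrum shaping, dispersion, fiber-mismatch) is out of
  scope, as is graph-based layer segmentation (the volume generator
  supplies approximate layer lines; only the refinement step is modelled).
* The uniform anterior retarder and uncorrelated Gaussian noise make the
  compensation and SNR analyses necessary-condition tests: failure on
  real data would not be caught here, success on real data is not proven.
* MD-based extension is biased low at low SNR (the axis becomes
  unobservable before the fibers end); the SNR–extension regression in
  the cohort stats exists precisely to surface that bias, and group
  comparisons should be read alongside it.
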