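"""Synthetic PS-OCT data generator with known ground truth.

Emulates the statistical structure the Henle-fiber analysis relies on:

* a radial axis-orientation pattern centered on the fovea (the fiber
  direction equals the azimuth about the foveal center, up to a global
  rotation offset that models the instrument's unknown axis reference);
* a "donut"-shaped retardation profile — zero at the foveal center,
  peaking near 2° eccentricity at ~9–11° single-pass retardation and
  decaying to zero at the lateral extension of the layer, with an
  optional nasal–temporal asymmetry of the elevated region;
* corruption of all en-face maps by one anterior retarder standing in
  for cornea plus RNFL, applied on the Poincaré sphere;
* additive Gaussian noise on every Stokes component at a configurable
  intensity SNR (dB);
* optional small layered volumes (dim inner retina, a bright reference
  plane, a bright polarization-preserving IS/OS band, a depolarizing RPE
  band, depth-decaying background noise) for the volume-level operators.

The radial profile is a raised-cosine bump: smooth, compactly supported,
and fully determined by (peak retardation, peak eccentricity, extension).
It is a surrogate — no functional form for the true profile is published.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .config import ConfigError, SceneGeometry
from .polarization import (Retarder, StokesMap, _rotate_quv, apply_retarder,
                           wrap_axis)

__all__ = [
    "HenleGroundTruth",
    "TruthRanges",
    "CohortParams",
    "EnfaceScene",
    "SubjectDataset",
    "SyntheticVolume",
    "make_truth",
    "radial_retardation_profile",
    "render_enface",
    "simulate_subject",
    "sample_cohort_truths",
    "render_volume",
]


@dataclass(frozen=True)
class HenleGroundTruth:
    """Ground-truth parameters of one synthetic eye."""

    fovea_center: Tuple[float, float]  # (x, y) px
    hfl_extension: float               # deg eccentricity, (0, 14]
    peak_retardation: float            # deg, [0, 45]
    peak_eccentricity: float           # deg, (0, hfl_extension)
    asymmetry_ratio: float = 1.0       # nasal-temporal / superior-inferior, >= 1
    anterior_retardation: float = 0.0  # deg
    anterior_axis: float = 0.0         # deg, [-90, 90)
    snr_db: float = np.inf             # 10*log10(signal intensity / noise std)
    rotation_offset: float = 0.0       # deg, global axis rotation
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.hfl_extension <= 14.0):
            raise ConfigError("hfl_extension must lie in (0°, 14°]")
        if not (0.0 < self.peak_eccentricity < self.hfl_extension):
            raise ConfigError("peak_eccentricity must lie in (0°, hfl_extension)")
        if not (0.0 <= self.peak_retardation <= 45.0):
            raise ConfigError("peak_retardation must lie in [0°, 45°]")
        if not (-90.0 <= self.anterior_axis < 90.0):
            raise ConfigError("anterior_axis must lie in [−90°, 90°)")
        if self.asymmetry_ratio < 1.0:
            raise ConfigError("asymmetry_ratio must be ≥ 1")


@dataclass(frozen=True)
class TruthRanges:
    """Uniform sampling ranges for :func:`make_truth`.

    Defaults reflect the healthy-eye study conditions: lateral extensions
    between 5° and 12°, peak retardation ~9–11° near 2° eccentricity, a
    mild nasal–temporal asymmetry, a cornea+RNFL surrogate retarder of a
    few tens of degrees, and en-face intensity SNR of 20–30 dB.
    """

    hfl_extension: Tuple[float, float] = (5.0, 12.0)
    peak_retardation: Tuple[float, float] = (9.0, 11.0)
    peak_eccentricity: Tuple[float, float] = (1.6, 2.4)
    asymmetry_ratio: Tuple[float, float] = (1.0, 1.3)
    anterior_retardation: Tuple[float, float] = (5.0, 30.0)
    anterior_axis: Tuple[float, float] = (-90.0, 90.0)
    snr_db: Tuple[float, float] = (20.0, 30.0)
    rotation_offset: Tuple[float, float] = (-90.0, 90.0)
    fovea_jitter_px: Tuple[float, float] = (20.0, 8.0)  # (±x, ±y) about grid center


_INVARIANT_BOUNDS = {
    "hfl_extension": (0.0, 14.0),
    "peak_retardation": (0.0, 45.0),
    "anterior_axis": (-90.0, 90.0),
}


def make_truth(ranges: Optional[TruthRanges] = None, seed: int = 0,
               geom: Optional[SceneGeometry] = None) -> HenleGroundTruth:
    """Sample a reproducible ground truth from uniform parameter ranges."""
    ranges = ranges or TruthRanges()
    geom = geom or SceneGeometry()
    for name, (lo, hi) in _INVARIANT_BOUNDS.items():
        a, b = getattr(ranges, name)
        if not (lo <= a <= b <= hi):
            raise ConfigError(f"range for {name} outside invariants: {(a, b)}")
    if ranges.asymmetry_ratio[0] < 1.0:
        raise ConfigError("asymmetry_ratio range must start at ≥ 1")
    rng = np.random.default_rng(seed)

    def draw(name):
        lo, hi = getattr(ranges, name)
        return float(rng.uniform(lo, hi))

    ext = draw("hfl_extension")
    peak_ecc = min(draw("peak_eccentricity"), 0.5 * ext)
    cx, cy = geom.center_px()
    jx, jy = ranges.fovea_jitter_px
    center = (cx + float(rng.uniform(-jx, jx)), cy + float(rng.uniform(-jy, jy)))
    return HenleGroundTruth(
        fovea_center=center,
        hfl_extension=ext,
        peak_retardation=draw("peak_retardation"),
        peak_eccentricity=peak_ecc,
        asymmetry_ratio=draw("asymmetry_ratio"),
        anterior_retardation=draw("anterior_retardation"),
        anterior_axis=draw("anterior_axis"),
        snr_db=draw("snr_db"),
        rotation_offset=draw("rotation_offset"),
        seed=seed,
    )


def radial_retardation_profile(ecc_deg, peak_retardation, peak_eccentricity,
                               extension):
    """Raised-cosine donut profile δ(e): 0 → peak at e_p → 0 at extension."""
    e = np.asarray(ecc_deg, dtype=float)
    out = np.zeros_like(e)
    rising = (e >= 0) & (e < peak_eccentricity)
    out[rising] = 0.5 * peak_retardation * (
        1.0 - np.cos(np.pi * e[rising] / peak_eccentricity))
    falling = (e >= peak_eccentricity) & (e < extension)
    out[falling] = 0.5 * peak_retardation * (
        1.0 + np.cos(np.pi * (e[falling] - peak_eccentricity)
                     / (extension - peak_eccentricity)))
    return out


@dataclass
class EnfaceScene:
    """Rendered en-face data for one acquisition of one eye."""

    is_os: StokesMap
    reference: StokesMap
    truth_retardation: np.ndarray  # pre-corruption sample retardation, deg
    truth_axis: np.ndarray         # pre-corruption sample axis, deg
    noise_sigma: float
    truth: HenleGroundTruth
    geom: SceneGeometry


def _sample_fields(truth: HenleGroundTruth, geom: SceneGeometry):
    """Noise-free ground-truth retardation and axis fields on the grid."""
    dx, dy = geom.offsets_deg(truth.fovea_center)
    ecc_eff = np.hypot(dx / truth.asymmetry_ratio, dy)
    ret = radial_retardation_profile(ecc_eff, truth.peak_retardation,
                                     truth.peak_eccentricity,
                                     truth.hfl_extension)
    phi = np.degrees(np.arctan2(-dx, dy)) % 360.0
    axis = wrap_axis((phi % 180.0) - 90.0 + truth.rotation_offset)
    return ret, axis


def _noise_sigma(truth: HenleGroundTruth, intensity: float) -> float:
    if np.isinf(truth.snr_db):
        return 0.0
    return intensity * 10.0 ** (-truth.snr_db / 10.0)


def render_enface(truth: HenleGroundTruth, geom: Optional[SceneGeometry] = None,
                  intensity: float = 1.0, ref_intensity: float = 0.5,
                  ) -> EnfaceScene:
    """Render corrupted IS/OS and anterior-reference Stokes maps.

    Both maps are transformed by the same anterior retarder; the IS/OS map
    additionally carries the Henle sample retarder.  Independent Gaussian
    noise of std ``intensity · 10^(−snr_db/10)`` is added to every Stokes
    component.  Validity marks pixels whose noisy intensity clears a
    5σ noise floor (everything, at noiseless settings).
    """
    geom = geom or SceneGeometry()
    ret, axis = _sample_fields(truth, geom)
    shape = geom.shape

    # sample retarder acting on the circular input (I, Q, U, V) = I·(1,1,0,0)
    one = np.full(shape, intensity)
    q, u, v = _rotate_quv(one.copy(), np.zeros(shape), np.zeros(shape), ret, axis)
    anterior = Retarder(truth.anterior_retardation, truth.anterior_axis)
    is_os = apply_retarder(StokesMap(one, q, u, v, surface="IS/OS"), anterior)

    rq, ru, rv = (np.full(shape, ref_intensity), np.zeros(shape), np.zeros(shape))
    reference = apply_retarder(
        StokesMap(np.full(shape, ref_intensity), rq, ru, rv, surface="reference"),
        anterior)

    sigma = _noise_sigma(truth, intensity)
    rng = np.random.default_rng([truth.seed, 1])
    for m, amp in ((is_os, intensity), (reference, ref_intensity)):
        s = sigma * amp / intensity
        if s > 0:
            m.i = m.i + rng.normal(0.0, s, shape)
            m.q = m.q + rng.normal(0.0, s, shape)
            m.u = m.u + rng.normal(0.0, s, shape)
            m.v = m.v + rng.normal(0.0, s, shape)
            m.valid = m.i > 5.0 * s
    return EnfaceScene(is_os, reference, ret, axis, sigma, truth, geom)


@dataclass
class SubjectDataset:
    """Input bundle for the correction pipeline: one acquisition."""

    is_os: StokesMap
    reference: StokesMap
    initial_center: Tuple[float, float]  # first-guess fovea position, px
    geom: SceneGeometry
    noise_sigma: float = 0.0
    truth: Optional[HenleGroundTruth] = None


def simulate_subject(truth: HenleGroundTruth, geom: Optional[SceneGeometry] = None,
                     center_offset_px: float = 15.0,
                     reference_perturbation: Tuple[float, float] = (0.0, 0.0),
                     ) -> SubjectDataset:
    """Render one acquisition and wrap it as pipeline input.

    The initial fovea estimate is displaced from the truth by up to
    ``center_offset_px`` in x and y (emulating the coarse RNFL-based first
    guess) so the iterative center refinement has real work to do.  The
    offset is expressed in pixels of the full-resolution 1024×250 grid
    (±15 px ↔ ±0.41° in x, ±1.26° in y) and converted to the actual
    grid, so the injected angular error is resolution-independent.
    ``reference_perturbation`` adds a systematic (dδ, dθ) error to the
    reference measurement, emulating imprecise anterior characterization;
    the offset grid search should recover its negation.
    """
    geom = geom or SceneGeometry()
    scene = render_enface(truth, geom)
    rng = np.random.default_rng([truth.seed, 2])
    off = rng.uniform(-center_offset_px, center_offset_px, 2)
    off_deg = (off[0] * 28.0 / 1024.0, off[1] * 21.0 / 250.0)
    init = (truth.fovea_center[0] + off_deg[0] / geom.deg_per_px_x,
            truth.fovea_center[1] + off_deg[1] / geom.deg_per_px_y)
    ref = scene.reference
    dd, dt = reference_perturbation
    if dd or dt:
        # rebuild the reference as if the anterior structures had been
        # measured with a systematic (dδ, dθ) error
        delta = np.clip(_ref_retardation(ref) + dd, 0.0, 179.0)
        theta = wrap_axis(_ref_axis(ref) + dt)
        q, u, v = _rotate_quv(ref.i.copy(), np.zeros(ref.shape),
                              np.zeros(ref.shape), delta, theta)
        ref = StokesMap(ref.i.copy(), q, u, v, surface=ref.surface,
                        valid=ref.valid.copy())
    return SubjectDataset(scene.is_os, ref, init, geom, scene.noise_sigma, truth)


def _ref_retardation(ref: StokesMap):
    from .polarization import retardation_from_stokes
    d = retardation_from_stokes(ref)
    return np.where(np.isfinite(d), d, 0.0)


def _ref_axis(ref: StokesMap):
    from .polarization import axis_from_stokes
    t = axis_from_stokes(ref)
    return np.where(np.isfinite(t), t, 0.0)


@dataclass(frozen=True)
class CohortParams:
    """Normal (mean, sd) truth distributions for one study group.

    Healthy defaults center the true extension near 8.8° with peak
    retardation ~9.5°; the glaucoma group has a slightly shorter extension
    and slightly lower peak retardation, mirroring the direction (not the
    clinical magnitude) of the reported group differences.
    """

    extension: Tuple[float, float] = (8.8, 1.2)
    peak_retardation: Tuple[float, float] = (9.5, 1.0)
    peak_eccentricity: Tuple[float, float] = (2.0, 0.2)
    snr_db: Tuple[float, float] = (24.0, 3.0)
    age: Tuple[float, float] = (60.0, 9.0)

    @classmethod
    def for_group(cls, group: str) -> "CohortParams":
        if group == "healthy":
            return cls()
        if group == "glaucoma":
            return cls(extension=(8.4, 1.2), peak_retardation=(9.0, 1.0),
                       age=(63.0, 9.5))
        raise ConfigError(f"unknown group {group!r}")


def sample_cohort_truths(n: int, group: str, seed: int,
                         params: Optional[CohortParams] = None,
                         geom: Optional[SceneGeometry] = None):
    """Sample (truth, age) pairs for a study group.

    Extensions are clipped to [5°, 12°] and SNR to [15, 32] dB so every
    subject stays within the regime the method is specified for.
    """
    params = params or CohortParams.for_group(group)
    geom = geom or SceneGeometry()
    rng = np.random.default_rng([seed, {"healthy": 11, "glaucoma": 13}.get(group, 17)])
    out = []
    cx, cy = geom.center_px()
    for k in range(n):
        ext = float(np.clip(rng.normal(*params.extension), 5.0, 12.0))
        peak = float(np.clip(rng.normal(*params.peak_retardation), 4.0, 14.0))
        pecc = float(np.clip(rng.normal(*params.peak_eccentricity), 1.0, 3.0))
        snr = float(np.clip(rng.normal(*params.snr_db), 15.0, 32.0))
        age = float(np.clip(rng.normal(*params.age), 20.0, 80.0))
        truth = HenleGroundTruth(
            fovea_center=(cx + float(rng.uniform(-20, 20)),
                          cy + float(rng.uniform(-8, 8))),
            hfl_extension=ext, peak_retardation=peak, peak_eccentricity=pecc,
            asymmetry_ratio=float(rng.uniform(1.0, 1.3)),
            anterior_retardation=float(rng.uniform(5.0, 30.0)),
            anterior_axis=float(rng.uniform(-90.0, 90.0)),
            snr_db=snr,
            rotation_offset=float(rng.uniform(-90.0, 90.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append((truth, age))
    return out


@dataclass
class SyntheticVolume:
    """Mini layered PS-OCT volume: arrays of shape (n_bscans, depth, nx)."""

    i: np.ndarray
    q: np.ndarray
    u: np.ndarray
    v: np.ndarray
    isos_line_true: np.ndarray   # (n_bscans, nx) int depth index
    isos_line_init: np.ndarray   # jittered segmentation line
    ref_bounds: Tuple[int, int]  # depth range holding the reference plane
    noise_sigma: float
    truth: HenleGroundTruth
    geom: SceneGeometry

    @property
    def shape(self):
        return self.i.shape

    def bscan(self, y: int) -> StokesMap:
        return StokesMap(self.i[y], self.q[y], self.u[y], self.v[y],
                         surface=f"bscan{y}")


def render_volume(truth: HenleGroundTruth, geom: SceneGeometry,
                  n_bscans: Optional[int] = None, depth_px: int = 96,
                  jitter_px: int = 3, include_layers: bool = True,
                  ) -> SyntheticVolume:
    """Render a small layered volume consistent with :func:`render_enface`.

    Layers (top to bottom): a dim inner-retina band; a brighter reference
    plane carrying the anterior-corrupted input state; a bright,
    polarization-preserving IS/OS band (5 px thick, the full corrupted
    sample state); a bright depolarizing RPE band with per-pixel random
    polarization states.  Background noise magnitude decays with depth.
    The IS/OS segmentation line returned as ``isos_line_init`` is jittered
    by ±``jitter_px`` to exercise the refinement step.
    """
    ny = geom.grid_px[1] if n_bscans is None else int(n_bscans)
    if ny != geom.grid_px[1]:
        geom = replace(geom, grid_px=(geom.grid_px[0], ny))
    if ny < 8 or depth_px < 64:
        raise ConfigError("volume needs n_bscans ≥ 8 and depth_px ≥ 64")
    nx = geom.grid_px[0]
    shape = (ny, depth_px, nx)
    rng = np.random.default_rng([truth.seed, 3])

    sigma = _noise_sigma(truth, 1.0)
    sigma0 = sigma if sigma > 0 else 0.0
    z = np.arange(depth_px, dtype=float)[None, :, None]
    decay = 1.0 - 0.3 * z / depth_px  # mild depth decay of the noise floor
    if sigma0 > 0:
        i = np.abs(rng.normal(0.0, sigma0, shape)) * decay
        q = rng.normal(0.0, sigma0, shape) * decay
        u = rng.normal(0.0, sigma0, shape) * decay
        v = rng.normal(0.0, sigma0, shape) * decay
    else:
        i = np.zeros(shape)
        q = np.zeros(shape)
        u = np.zeros(shape)
        v = np.zeros(shape)

    z_inner = int(0.15 * depth_px)
    z_ref = int(0.35 * depth_px)
    z_isos0 = int(0.6 * depth_px)
    xs = np.arange(nx)
    tilt = np.round(2.0 * np.sin(2 * np.pi * xs / max(nx, 2))).astype(int)
    isos_line = np.broadcast_to(z_isos0 + tilt, (ny, nx)).copy()

    if include_layers:
        ret, axis = _sample_fields(truth, geom)
        one = np.ones((ny, nx))
        sq, su, sv = _rotate_quv(one.copy(), np.zeros((ny, nx)),
                                 np.zeros((ny, nx)), ret, axis)
        anterior = Retarder(truth.anterior_retardation, truth.anterior_axis)
        isos_state = apply_retarder(StokesMap(one, sq, su, sv), anterior)
        ref_state = apply_retarder(
            StokesMap(one.copy(), one.copy(), np.zeros((ny, nx)),
                      np.zeros((ny, nx))), anterior)

        yy, xx = np.meshgrid(np.arange(ny), xs, indexing="ij")
        # dim inner retina (polarization-preserving, anterior-corrupted input)
        for dz in range(3):
            i[:, z_inner + dz, :] += 0.25
            q[:, z_inner + dz, :] += 0.25 * ref_state.q
            u[:, z_inner + dz, :] += 0.25 * ref_state.u
            v[:, z_inner + dz, :] += 0.25 * ref_state.v
        # reference plane (brightest pixel between RNFL-GCL and INL-OPL)
        i[:, z_ref, :] += 0.5
        q[:, z_ref, :] += 0.5 * ref_state.q
        u[:, z_ref, :] += 0.5 * ref_state.u
        v[:, z_ref, :] += 0.5 * ref_state.v
        # IS/OS band, 5 px thick, carrying the full sample signal
        for dz in range(-2, 3):
            zz = np.clip(isos_line + dz, 0, depth_px - 1)
            amp = 1.0 if dz == 0 else 0.8
            i[yy, zz, xx] += amp
            q[yy, zz, xx] += amp * isos_state.q
            u[yy, zz, xx] += amp * isos_state.u
            v[yy, zz, xx] += amp * isos_state.v
        # depolarizing RPE: bright, per-pixel random states
        for dz in range(5, 9):
            zz = np.clip(isos_line + dz, 0, depth_px - 1)
            nvec = rng.normal(size=(3, ny, nx))
            nvec /= np.linalg.norm(nvec, axis=0, keepdims=True)
            i[yy, zz, xx] += 0.9
            q[yy, zz, xx] += 0.9 * nvec[0]
            u[yy, zz, xx] += 0.9 * nvec[1]
            v[yy, zz, xx] += 0.9 * nvec[2]

    jit = (rng.integers(-jitter_px, jitter_px + 1, size=(ny, nx))
           if jitter_px > 0 else np.zeros((ny, nx), int))
    init = np.clip(isos_line + jit, 0, depth_px - 1)
    return SyntheticVolume(i, q, u, v, isos_line, init,
                           (z_inner + 3, z_ref + 4), sigma0, truth, geom)
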