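"""Volume-level operators: thresholds, IS/OS refinement, en-face extraction.

These turn a (synthetic) PS-OCT volume into the en-face Stokes maps the
pattern analysis consumes.  All operators act per A-scan, independently.

The intensity noise threshold is estimated from the central B-scan: the
pixels are sorted by intensity, the mean Ī and standard deviation σ_I of
the darkest 80% are computed (the retinal signal is assumed to sit in
the brightest 20%), the first-row threshold is Ī + 7σ_I, and it
decreases linearly with depth by 0.08% of σ_I per pixel row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .polarization import StokesMap, dopu
from .synthetic import SyntheticVolume

log = logging.getLogger(__name__)

__all__ = ["ThresholdProfile", "threshold_profile", "dopu_volume",
           "refine_isos", "extract_enface", "reference_measurement",
           "estimate_snr"]


@dataclass(frozen=True)
class ThresholdProfile:
    """Depth-dependent intensity threshold: base − row·decay·σ_I."""

    base: float
    sigma: float
    depth_px: int
    decay_frac: float = 0.0008  # fraction of σ_I removed per pixel row

    def at(self, row):
        return self.base - np.asarray(row, dtype=float) * self.decay_frac * self.sigma

    def profile(self) -> np.ndarray:
        return self.at(np.arange(self.depth_px))


def threshold_profile(central_bscan: np.ndarray,
                      depth_px: Optional[int] = None) -> ThresholdProfile:
    """Noise threshold from the darkest 80% of a central B-scan."""
    img = np.asarray(central_bscan, dtype=float)
    if img.size == 0:
        raise ValueError("empty B-scan")
    flat = np.sort(img.ravel())
    dark = flat[: max(1, int(0.8 * flat.size))]
    mean, sigma = float(dark.mean()), float(dark.std())
    if sigma == 0.0:
        log.warning("constant B-scan: σ_I = 0, threshold equals the mean")
        return ThresholdProfile(mean, 0.0, depth_px or img.shape[0])
    return ThresholdProfile(mean + 7.0 * sigma, sigma,
                            depth_px or img.shape[0])


def dopu_volume(vol: SyntheticVolume, kernel: Tuple[int, int] = (10, 10),
                ) -> np.ndarray:
    """DOPU per B-scan (axial × lateral kernel), shape (ny, depth, nx)."""
    out = np.empty_like(vol.i)
    for y in range(vol.shape[0]):
        out[y] = np.nan_to_num(dopu(vol.bscan(y), kernel), nan=0.0)
    return out


def refine_isos(vol: SyntheticVolume, dopu_map: np.ndarray,
                initial_line: np.ndarray, dopu_cut: float = 0.75,
                halfwidth: int = 8):
    """Correct the IS/OS segmentation line per A-scan.

    Pixels with DOPU below ``dopu_cut`` (depolarizing RPE) are excluded;
    the brightest remaining pixel within ±``halfwidth`` of the initial
    line becomes the corrected position.  A-scans with no candidate keep
    their initial position and are flagged.
    Returns (refined line, flagged mask), both shape (ny, nx).
    """
    ny, depth, nx = vol.shape
    line = np.asarray(initial_line)
    if np.any(line < 0) or np.any(line >= depth):
        raise ValueError("initial line outside volume depth")
    offs = np.arange(-halfwidth, halfwidth + 1)
    # (ny, nx, 2W+1) window depth indices, clipped at the volume edge
    zz = np.clip(line[..., None] + offs, 0, depth - 1)
    ii = np.take_along_axis(np.moveaxis(vol.i, 1, 2), zz, axis=2)
    dd = np.take_along_axis(np.moveaxis(dopu_map, 1, 2), zz, axis=2)
    ok = dd >= dopu_cut
    flagged = ~ok.any(axis=2)
    score = np.where(ok, ii, -np.inf)
    pick = np.argmax(score, axis=2)  # first max → shallowest tie-break
    refined = np.take_along_axis(zz, pick[..., None], axis=2)[..., 0]
    refined = np.where(flagged, line, refined)
    return refined, flagged


def extract_enface(vol: SyntheticVolume, line: np.ndarray, band_px: int = 5,
                   threshold: Optional[ThresholdProfile] = None) -> StokesMap:
    """Average Stokes components over a depth band around the IS/OS line.

    ``band_px`` pixels in depth (~10 µm at 2 µm/px) centered on the line
    are averaged per A-scan, keeping only pixels above the depth-dependent
    intensity threshold; A-scans whose whole band is sub-threshold become
    invalid pixels of the en-face map.
    """
    ny, depth, nx = vol.shape
    half = band_px // 2
    offs = np.arange(-half, band_px - half)
    zz = np.clip(np.asarray(line)[..., None] + offs, 0, depth - 1)

    def take(a):
        return np.take_along_axis(np.moveaxis(a, 1, 2), zz, axis=2)

    ii = take(vol.i)
    ok = np.ones_like(ii, dtype=bool)
    if threshold is not None:
        ok = ii >= threshold.at(zz)
    cnt = ok.sum(axis=2)
    safe = np.maximum(cnt, 1)
    comps = []
    for a in (vol.i, vol.q, vol.u, vol.v):
        w = np.where(ok, take(a), 0.0)
        comps.append(w.sum(axis=2) / safe)
    return StokesMap(*comps, surface="IS/OS", valid=cnt > 0)


def reference_measurement(vol: SyntheticVolume,
                          layer_bounds: Tuple[int, int]) -> StokesMap:
    """Stokes state of the brightest pixel in a depth range, per A-scan.

    The range models RNFL-GCL … INL-OPL (posterior to the RNFL, anterior
    to HFL).  Ties go to the shallower pixel for reproducibility.
    """
    lo, hi = layer_bounds
    if not (0 <= lo < hi <= vol.shape[1]):
        raise ValueError("layer bounds must be ordered and inside the volume")
    sub = vol.i[:, lo:hi, :]
    pick = np.argmax(sub, axis=1) + lo  # (ny, nx); first max = shallowest
    yy, xx = np.meshgrid(np.arange(vol.shape[0]), np.arange(vol.shape[2]),
                         indexing="ij")
    return StokesMap(vol.i[yy, pick, xx], vol.q[yy, pick, xx],
                     vol.u[yy, pick, xx], vol.v[yy, pick, xx],
                     surface="reference")


def estimate_snr(enface_intensity: np.ndarray, threshold_at_line,
                 valid: Optional[np.ndarray] = None) -> float:
    """Mean intensity-to-threshold ratio over valid en-face pixels."""
    i = np.asarray(enface_intensity, dtype=float)
    thr = np.broadcast_to(np.asarray(threshold_at_line, dtype=float), i.shape)
    ok = np.ones(i.shape, bool) if valid is None else np.asarray(valid, bool)
    ok = ok & (thr > 0)
    if not ok.any():
        raise ValueError("no valid pixels for SNR estimation")
    return float(np.mean(i[ok] / thr[ok]))
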