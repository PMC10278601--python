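"""Circumferential retardation profile and its scalar summaries.

After full correction, the retardation map shows the annular ("donut")
pattern of elevated retardation around the fovea.  The map is smoothed by
averaging Stokes vectors in 9×9 px windows — locally, where the axis
orientation is approximately constant, so the averaging is bias-free —
and the smoothed retardation is then averaged circumferentially around
the determined foveal center.  The circumferential stage must average
retardation values, not Stokes vectors: around a full ring the fiber
axis sweeps every orientation, so ring-averaged transverse Stokes
components cancel and would collapse the retardation toward zero.

Scalar summaries: the peak retardation and its eccentricity (typically
~9° near 2°), the area under the curve between 1° and 8° eccentricity,
and the mean retardation per 1°-wide annulus from 1–2° to 7–8°.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .config import SceneGeometry
from .polarization import StokesMap, average_stokes, retardation_from_stokes

__all__ = ["RetardationProfile", "ProfileMetrics", "smooth_stokes",
           "circumferential_average", "profile_metrics"]

ANNULI_DEG = [(k, k + 1) for k in range(1, 8)]  # 1–2° … 7–8°


def smooth_stokes(s: StokesMap, kernel: Tuple[int, int] = (9, 9)) -> StokesMap:
    """Componentwise windowed Stokes mean honoring the validity mask."""
    return average_stokes(s, kernel=kernel)


@dataclass
class RetardationProfile:
    """Circumferentially averaged retardation vs eccentricity."""

    eccentricity: np.ndarray  # bin centers, deg
    retardation: np.ndarray   # deg, NaN for empty bins
    counts: np.ndarray
    annulus_means: np.ndarray  # 1°-ring means for 1–2° … 7–8°, deg
    center: Tuple[float, float]


@dataclass
class ProfileMetrics:
    peak: float       # max retardation over the profile, deg
    peak_ecc: float   # eccentricity of the max, deg
    auc_1_8: float    # trapezoid area under the curve on [1°, 8°], deg·deg
    annulus_means: np.ndarray
    auc_defined: bool = True


def _binned_mean(values, valid, ecc, edges):
    """Mean of ``values`` per eccentricity bin; NaN for empty bins."""
    nb = len(edges) - 1
    idx = np.searchsorted(edges, ecc.ravel(), side="right") - 1
    ok = valid.ravel() & np.isfinite(values.ravel()) & (idx >= 0) & (idx < nb)
    idx = idx[ok]
    sums = np.bincount(idx, weights=values.ravel()[ok], minlength=nb)
    cnt = np.bincount(idx, minlength=nb)
    ret = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
    return ret, cnt


def circumferential_average(s: StokesMap, center, geom: SceneGeometry,
                            bin_width: float = 0.25, max_ecc: float = 14.0,
                            smooth: Optional[Tuple[int, int]] = (9, 9),
                            ) -> RetardationProfile:
    """Average retardation circumferentially around the foveal center.

    ``s`` is the fully corrected IS/OS Stokes map; it is smoothed with
    ``smooth`` (pass None to skip), converted to retardation, and the
    retardation values are averaged per eccentricity bin in degree
    space.  Per-annulus means for the 1°-wide rings 1–2° … 7–8° come
    from the same retardation map.
    """
    if smooth is not None:
        s = smooth_stokes(s, smooth)
    ret_map = retardation_from_stokes(s)
    ecc, _ = geom.polar_deg(center)
    edges = np.arange(0.0, max_ecc + bin_width / 2, bin_width)
    ret, cnt = _binned_mean(ret_map, s.valid, ecc, edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ring_edges = np.array([a for a, _ in ANNULI_DEG] + [ANNULI_DEG[-1][1]],
                          dtype=float)
    ring_ret, _ = _binned_mean(ret_map, s.valid, ecc, ring_edges)
    return RetardationProfile(centers, ret, cnt, ring_ret, tuple(center))


def profile_metrics(profile: RetardationProfile) -> ProfileMetrics:
    """Peak, peak eccentricity, AUC(1°–8°) and per-annulus means.

    The AUC uses the trapezoid rule on bin centers within [1°, 8°];
    gaps (empty bins) inside that range leave the AUC undefined.
    """
    ret, ecc = profile.retardation, profile.eccentricity
    if not np.any(np.isfinite(ret)):
        raise ValueError("profile has no defined bins")
    k = int(np.nanargmax(ret))
    band = (ecc >= 1.0) & (ecc <= 8.0)
    defined = bool(band.any()) and bool(np.all(np.isfinite(ret[band])))
    auc = float(np.trapezoid(ret[band], ecc[band])) if defined else np.nan
    return ProfileMetrics(peak=float(np.nanmax(ret)), peak_ecc=float(ecc[k]),
                          auc_1_8=auc, annulus_means=profile.annulus_means,
                          auc_defined=defined)
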