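"""Azimuthal mean-deviation (MD) statistic and the correction pipeline.

Henle fibers emerge radially from the fovea, so on a circle around the
foveal center the measured optic-axis orientation increases linearly with
the azimuth angle φ.  Axis orientation is axial data (θ and θ+180° are
the same physical orientation), so θ is embedded on the unit circle with
the doubled angle, Z(θ) = e^{i·2θ}; the ideal radial pattern, anchored so
that θ(φ=0) = −90°, then performs two full oscillations of Re Z and Im Z
as φ runs 0°→360°.

The MD of an annulus is the mean, over 360 one-degree azimuthal segments,
of the L1 distance between the segment-averaged Z and the ideal pattern:

    MD = mean_s ( |Re Z̄_s − Re Z_ideal(φ_s)| + |Im Z̄_s − Im Z_ideal(φ_s)| )

A perfect radial pattern gives MD = 0; a completely random axis map gives
MD = 4/π ≈ 1.27 (the segment means vanish and E|cos| + E|sin| = 4/π),
the "noise floor" of ~1.3.  HFL is considered present while MD stays
below the empirical cut-off of 0.65, half the noise floor.

Four corrections precede the per-annulus analysis: (1) a global axis
rotation fixing the unknown axis reference, found from the +90°→−90°
wrap in the 1–2° annulus; (2) iterative refinement of the fovea center by
exhaustive MD minimization over a 31×31 px window; (3) a ±5° grid search
over retardation/axis offsets of the anterior compensation; (4) a second
center refinement.  All minimizations target MD in the 1–2° annulus,
where HFL retardation is strongest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import SceneGeometry
from .polarization import (PolarizationMaps, StokesMap, axis_from_stokes,
                           compensate_anterior, retardation_from_stokes,
                           wrap_axis)

__all__ = [
    "AnnulusSpec",
    "AzimuthalProfile",
    "HenleMDProfile",
    "HenleResult",
    "ideal_pattern",
    "axis_to_complex",
    "segment_means",
    "compute_md",
    "md_profile",
    "rotation_correction",
    "refine_center",
    "offset_search",
    "full_correction",
    "hfl_extension",
    "select_best_repeat",
]

N_ANNULI = 14
N_SEGMENTS = 360
MD_CUTOFF = 0.65
MD_ANNULUS = (1.0, 2.0)  # all corrections minimize MD in this annulus


def axis_to_complex(theta_deg):
    """Embed axis orientation on the unit circle: Z = e^{i·2θ}.

    The doubled angle makes the embedding respect the half-turn
    periodicity of axis data (θ and θ+180° map to the same Z), the
    standard treatment of axial quantities in circular statistics.
    """
    return np.exp(1j * np.deg2rad(2.0 * np.asarray(theta_deg, dtype=float)))


def ideal_pattern(phi_deg):
    """Ideal radial-pattern Z at azimuth φ: θ_ideal(φ) = (φ mod 180°) − 90°."""
    theta = (np.asarray(phi_deg, dtype=float) % 180.0) - 90.0
    return axis_to_complex(theta)


@dataclass(frozen=True)
class AnnulusSpec:
    """One annulus: 1°-wide ring of 360 azimuthal segments, degree space."""

    inner_radius: float
    outer_radius: float
    center: Tuple[float, float]
    geometry: SceneGeometry
    n_segments: int = N_SEGMENTS


@dataclass
class AzimuthalProfile:
    """Per-segment complex means around one annulus."""

    z_mean: np.ndarray  # (n_segments,) complex; NaN where empty
    counts: np.ndarray  # (n_segments,) int
    annulus: AnnulusSpec


@dataclass
class HenleMDProfile:
    """MD per 1°-wide annulus (index k spans k..k+1 degrees eccentricity)."""

    md: np.ndarray                      # (n_annuli,), NaN where undefined
    center_used: Tuple[float, float]
    rotation_used: float
    offsets_used: Tuple[float, float]


@dataclass
class HenleResult:
    profile: HenleMDProfile
    maps: PolarizationMaps
    stokes: StokesMap


def _crop_window(center, geom: SceneGeometry, r_out: float, shape):
    """Slices of the sub-window containing the disc of radius r_out (deg)."""
    cx, cy = center
    rx = int(np.ceil(r_out / geom.deg_per_px_x)) + 2
    ry = int(np.ceil(r_out / geom.deg_per_px_y)) + 2
    x0 = max(0, int(np.floor(cx)) - rx)
    x1 = min(shape[1], int(np.ceil(cx)) + rx + 1)
    y0 = max(0, int(np.floor(cy)) - ry)
    y1 = min(shape[0], int(np.ceil(cy)) + ry + 1)
    return slice(y0, y1), slice(x0, x1)


def _segment_sums(z, valid, center, geom, r_in, r_out, n_segments,
                  y0=0, x0=0):
    """Complex per-segment sums and counts for pixels in [r_in, r_out)."""
    ecc, phi = geom.polar_deg(center, y0=y0, x0=x0, shape=z.shape)
    sel = valid & (ecc >= r_in) & (ecc < r_out)
    seg = np.minimum((phi[sel] * n_segments / 360.0).astype(np.intp),
                     n_segments - 1)
    zv = z[sel]
    cnt = np.bincount(seg, minlength=n_segments)
    zr = np.bincount(seg, weights=zv.real, minlength=n_segments)
    zi = np.bincount(seg, weights=zv.imag, minlength=n_segments)
    return zr + 1j * zi, cnt


def segment_means(axis_deg, valid, annulus: AnnulusSpec) -> AzimuthalProfile:
    """Segment-averaged Z around an annulus; empty segments are NaN."""
    axis_deg = np.asarray(axis_deg, dtype=float)
    ys, xs = _crop_window(annulus.center, annulus.geometry,
                          annulus.outer_radius, np.shape(axis_deg))
    ax = axis_deg[ys, xs]
    ok = valid[ys, xs] & np.isfinite(ax)
    z = np.where(ok, axis_to_complex(np.nan_to_num(ax)), 0.0)
    sums, cnt = _segment_sums(z, ok, annulus.center,
                              annulus.geometry, annulus.inner_radius,
                              annulus.outer_radius, annulus.n_segments,
                              y0=ys.start, x0=xs.start)
    with np.errstate(invalid="ignore", divide="ignore"):
        zbar = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan + 0j)
    return AzimuthalProfile(zbar, cnt, annulus)


def _md_from_segments(zbar, cnt, n_segments, min_frac=0.5):
    nonempty = cnt > 0
    if nonempty.sum() < min_frac * n_segments:
        return np.nan
    phi_s = (np.arange(n_segments) + 0.5) * (360.0 / n_segments)
    zid = ideal_pattern(phi_s)
    d = (np.abs(zbar.real - zid.real) + np.abs(zbar.imag - zid.imag))
    return float(np.mean(d[nonempty]))


def compute_md(axis_deg, valid, annulus: AnnulusSpec, min_frac=0.5) -> float:
    """MD of one annulus; NaN when more than half the segments are empty."""
    prof = segment_means(axis_deg, valid, annulus)
    return _md_from_segments(prof.z_mean, prof.counts, annulus.n_segments,
                             min_frac)


def md_profile(axis_deg, valid, center, geom: SceneGeometry,
               n_annuli: int = N_ANNULI, n_segments: int = N_SEGMENTS,
               min_frac: float = 0.5) -> np.ndarray:
    """MD for all annuli 0–1°, 1–2°, …, (n−1)–n° in one pass."""
    ok = valid & np.isfinite(axis_deg)
    z = np.where(ok, axis_to_complex(np.nan_to_num(axis_deg)), 0.0)
    ys, xs = _crop_window(center, geom, float(n_annuli), np.shape(axis_deg))
    ecc, phi = geom.polar_deg(center, y0=ys.start, x0=xs.start,
                              shape=z[ys, xs].shape)
    sel = ok[ys, xs] & (ecc < n_annuli)
    ann = ecc[sel].astype(np.intp)
    seg = np.minimum((phi[sel] * n_segments / 360.0).astype(np.intp),
                     n_segments - 1)
    idx = ann * n_segments + seg
    m = n_annuli * n_segments
    zv = z[ys, xs][sel]
    cnt = np.bincount(idx, minlength=m).reshape(n_annuli, n_segments)
    zr = np.bincount(idx, weights=zv.real, minlength=m)
    zi = np.bincount(idx, weights=zv.imag, minlength=m)
    zbar = ((zr + 1j * zi).reshape(n_annuli, n_segments)
            / np.maximum(cnt, 1))
    out = np.empty(n_annuli)
    for k in range(n_annuli):
        out[k] = _md_from_segments(np.where(cnt[k] > 0, zbar[k], np.nan),
                                   cnt[k], n_segments, min_frac)
    return out


def _md_1_2(axis_deg, valid, center, geom, n_segments=N_SEGMENTS):
    ann = AnnulusSpec(*MD_ANNULUS, center=tuple(center), geometry=geom,
                      n_segments=n_segments)
    return compute_md(axis_deg, valid, ann)


class _PhasorGrid:
    """Precomputed phasor map for repeated MD evaluation at moving centers.

    The axis map enters the MD only through Z = e^{i2θ}, which is
    independent of the trial center, so it is computed once; per center
    only the polar coordinates and segment sums are redone.
    """

    def __init__(self, axis_deg, valid, geom, y0=0, x0=0):
        axis_deg = np.asarray(axis_deg, dtype=float)
        self.ok = valid & np.isfinite(axis_deg)
        self.z = np.where(self.ok, axis_to_complex(np.nan_to_num(axis_deg)), 0.0)
        self.geom = geom
        self.y0, self.x0 = y0, x0
        ny, nx = axis_deg.shape
        self.x_deg = np.arange(x0, x0 + nx) * geom.deg_per_px_x
        self.y_deg = np.arange(y0, y0 + ny) * geom.deg_per_px_y

    def segment_sums(self, center, r_in, r_out, n_segments=N_SEGMENTS):
        g = self.geom
        # bounding box of the annulus within the stored window
        j0 = max(0, int((center[0] - self.x0) - r_out / g.deg_per_px_x) - 1)
        j1 = min(self.z.shape[1], int((center[0] - self.x0)
                                      + r_out / g.deg_per_px_x) + 2)
        i0 = max(0, int((center[1] - self.y0) - r_out / g.deg_per_px_y) - 1)
        i1 = min(self.z.shape[0], int((center[1] - self.y0)
                                      + r_out / g.deg_per_px_y) + 2)
        dx = (self.x_deg[j0:j1] - center[0] * g.deg_per_px_x)[None, :]
        dy = (center[1] * g.deg_per_px_y - self.y_deg[i0:i1])[:, None]
        ecc2 = dx * dx + dy * dy
        sel = self.ok[i0:i1, j0:j1] & (ecc2 >= r_in * r_in) & (ecc2 < r_out * r_out)
        # azimuth only for the selected annulus pixels
        dxs = np.broadcast_to(dx, sel.shape)[sel]
        dys = np.broadcast_to(dy, sel.shape)[sel]
        phi = np.degrees(np.arctan2(-dxs, dys)) % 360.0
        seg = np.minimum((phi * n_segments / 360.0).astype(np.intp),
                         n_segments - 1)
        zv = self.z[i0:i1, j0:j1][sel]
        cnt = np.bincount(seg, minlength=n_segments)
        zr = np.bincount(seg, weights=zv.real, minlength=n_segments)
        zi = np.bincount(seg, weights=zv.imag, minlength=n_segments)
        return zr + 1j * zi, cnt

    def md(self, center, r_in=MD_ANNULUS[0], r_out=MD_ANNULUS[1],
           n_segments=N_SEGMENTS, rotation=0.0, min_frac=0.5):
        sums, cnt = self.segment_sums(center, r_in, r_out, n_segments)
        zbar = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan + 0j)
        if rotation:
            zbar = zbar * np.exp(1j * np.deg2rad(2.0 * rotation))
        return _md_from_segments(zbar, cnt, n_segments, min_frac)

    def md_min_rotation(self, center, r_in=MD_ANNULUS[0], r_out=MD_ANNULUS[1],
                        n_segments=N_SEGMENTS, min_frac=0.5):
        """(MD, rotation) minimized over all 180 integer axis rotations.

        A global rotation c multiplies every segment mean by e^{i2c}, so
        the whole sweep is a broadcast over the segment means.
        """
        sums, cnt = self.segment_sums(center, r_in, r_out, n_segments)
        nonempty = cnt > 0
        if nonempty.sum() < min_frac * n_segments:
            return np.nan, 0.0
        zbar = sums[nonempty] / cnt[nonempty]
        phi_s = (np.flatnonzero(nonempty) + 0.5) * (360.0 / n_segments)
        zid = ideal_pattern(phi_s)
        cands = np.arange(-90.0, 90.0)
        rotor = np.exp(1j * np.deg2rad(2.0 * cands))
        d = zbar[None, :] * rotor[:, None] - zid[None, :]
        mds = np.mean(np.abs(d.real) + np.abs(d.imag), axis=1)
        k = int(np.argmin(mds))
        return float(mds[k]), float(cands[k])


def _crop_view(axis_deg, valid, center, geom, r_out):
    """Cropped (axis, valid, center-in-crop) view covering radius r_out."""
    axis_deg = np.asarray(axis_deg, dtype=float)
    ys, xs = _crop_window(center, geom, r_out, axis_deg.shape)
    sub_center = (center[0] - xs.start, center[1] - ys.start)
    return axis_deg[ys, xs], valid[ys, xs], sub_center


def rotation_correction(axis_deg, valid, center, geom: SceneGeometry,
                        n_segments: int = N_SEGMENTS):
    """Global axis rotation anchoring the pattern at θ(φ=0) = −90°.

    The instrument only measures a relative axis orientation, so the whole
    map may be rotated by an unknown constant.  The required rotation is
    read off the azimuthal position of the +90°→−90° wrap of the
    segment-mean axis in the 1–2° annulus, then refined over ±3° by MD
    minimization.  If no wrap is discernible (e.g. pure noise), the
    rotation minimizing MD over all 180 integer candidates is used; if
    the MD landscape is flat as well, the map is returned unrotated.
    Returns (rotated axis map, rotation in degrees).
    """
    ann = AnnulusSpec(*MD_ANNULUS, center=tuple(center), geometry=geom,
                      n_segments=n_segments)
    prof = segment_means(axis_deg, valid, ann)
    ok = prof.counts > 0
    cands: List[float] = []
    if ok.sum() >= 0.5 * n_segments:
        # axial (doubled-angle) segment-mean orientation, [−90°, 90°)
        theta_bar = wrap_axis(0.5 * np.degrees(np.angle(prof.z_mean)))
        idx = np.flatnonzero(ok)
        tb = theta_bar[idx]
        diffs = np.roll(tb, -1) - tb
        j = int(np.argmin(diffs))
        if diffs[j] < -90.0:  # wrap detected between segments idx[j], idx[j+1]
            phi_jump = (idx[(j + 1) % len(idx)]) * (360.0 / n_segments)
            c0 = wrap_axis(phi_jump)
            cands = [wrap_axis(c0 + d) for d in range(-3, 4)]
    if not cands:
        cands = [float(c) for c in np.arange(-90.0, 90.0)]
    # a global rotation c multiplies every segment mean by e^{i2c}, so all
    # candidates are scored on the segment means already in hand
    rotor = np.exp(1j * np.deg2rad(2.0 * np.asarray(cands)))
    mds = np.array([
        _md_from_segments(prof.z_mean * r, prof.counts, n_segments)
        for r in rotor])
    if not np.any(np.isfinite(mds)) or (np.nanmax(mds) - np.nanmin(mds) < 1e-9):
        warnings.warn("no discernible Henle pattern; rotation left at 0°")
        return np.asarray(axis_deg, dtype=float).copy(), 0.0
    best = float(cands[int(np.nanargmin(mds))])
    rotated = np.where(np.isfinite(axis_deg), wrap_axis(axis_deg + best), np.nan)
    return rotated, best


def refine_center(axis_deg, valid, initial_center, geom: SceneGeometry,
                  window_px: int = 31, max_iter: int = 20,
                  n_segments: int = N_SEGMENTS):
    """Iterative exhaustive fovea-center search minimizing MD in 1–2°.

    Every pixel in a ``window_px`` × ``window_px`` window around the
    current center is tried as a new center; the minimum-MD pixel becomes
    the new center; iterate to a fixed point.  Ties are broken by the
    smallest (|Δy|, then |Δx|) displacement from the current center.
    Returns (center, md).
    """
    half = window_px // 2
    cx, cy = float(initial_center[0]), float(initial_center[1])
    cur_md = _md_1_2(axis_deg, valid, (cx, cy), geom, n_segments)
    # candidate order encodes the tie-break: sorted by (|dy|, |dx|, dy, dx)
    offs = sorted(((dy, dx) for dy in range(-half, half + 1)
                   for dx in range(-half, half + 1)),
                  key=lambda o: (abs(o[0]), abs(o[1]), o[0], o[1]))
    margin = half * max(geom.deg_per_px_x, geom.deg_per_px_y)
    for _ in range(max_iter):
        ys, xs = _crop_window((cx, cy), geom, MD_ANNULUS[1] + margin + 0.5,
                              np.shape(axis_deg))
        grid = _PhasorGrid(np.asarray(axis_deg, float)[ys, xs],
                           valid[ys, xs], geom, y0=ys.start, x0=xs.start)
        best = (np.inf, 0.0, 0.0)
        for dy, dx in offs:
            md = grid.md((cx + dx, cy + dy), n_segments=n_segments)
            if np.isfinite(md) and md < best[0] - 1e-15:
                best = (md, dx, dy)
        if not np.isfinite(best[0]):
            warnings.warn("center refinement found no defined MD; keeping start")
            return (cx, cy), cur_md
        if best[1] == 0.0 and best[2] == 0.0:
            return (cx, cy), best[0]
        cx, cy = cx + best[1], cy + best[2]
        cur_md = best[0]
    warnings.warn("center refinement did not converge; returning best-so-far")
    return (cx, cy), cur_md


def offset_search(target: StokesMap, reference: StokesMap, rotation, center,
                  geom: SceneGeometry, offset_range: float = 5.0,
                  offset_step: float = 1.0, n_segments: int = N_SEGMENTS):
    """Grid search over anterior-compensation offsets (dδ, dθ).

    The en-face maps are recompensated for every offset combination on a
    ±``offset_range`` grid in ``offset_step`` increments (11×11 by
    default) and the combination minimizing MD in the 1–2° annulus is
    selected.  Ties are broken by the smallest |dδ|+|dθ|, then
    lexicographically.

    ``rotation`` is the global axis-rotation constant applied before the
    MD is evaluated; pass ``None`` to re-fit the rotation per candidate
    (an axis offset dθ and the rotation anchor are partly degenerate, so
    holding a stale rotation fixed can bias the argmin).
    Returns ((dδ, dθ), md_at_minimum, rotation_at_minimum).
    """
    ys, xs = _crop_window(center, geom, MD_ANNULUS[1] + 0.5, target.shape)
    tgt = target.crop(ys, xs)
    ref = reference.crop(ys, xs)
    sub_center = (center[0] - xs.start, center[1] - ys.start)
    grid = np.arange(-offset_range, offset_range + 0.5 * offset_step,
                     offset_step)
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for dd in grid:
            for dt in grid:
                comp = compensate_anterior(tgt, ref, (dd, dt))
                ax = axis_from_stokes(comp)
                if rotation is None:
                    ax, rot = rotation_correction(ax, comp.valid, sub_center,
                                                  geom, n_segments)
                else:
                    rot = float(rotation)
                    ax = np.where(np.isfinite(ax), wrap_axis(ax + rot), np.nan)
                md = _md_1_2(ax, comp.valid, sub_center, geom, n_segments)
                if np.isfinite(md):
                    results.append((md, abs(dd) + abs(dt), dd, dt, rot))
    if not results:
        raise ValueError("offset search: MD undefined for every candidate")
    md, _, dd, dt, rot = min(results)
    return (float(dd), float(dt)), float(md), float(rot)


def _joint_center_rotation(axis_deg, valid, initial_center,
                           geom: SceneGeometry, window_px: int = 31,
                           n_segments: int = N_SEGMENTS, max_iter: int = 20):
    """Exhaustive center search scored by rotation-minimized MD in 1–2°.

    Decouples the fovea-center and rotation-anchor corrections: each
    candidate center is scored by the best MD over all 180 integer
    rotations, so a bad rotation guess cannot mislead the center search.
    Returns (center, rotation).
    """
    half = window_px // 2
    cx, cy = float(initial_center[0]), float(initial_center[1])
    offs = sorted(((dy, dx) for dy in range(-half, half + 1)
                   for dx in range(-half, half + 1)),
                  key=lambda o: (abs(o[0]), abs(o[1]), o[0], o[1]))
    margin = half * max(geom.deg_per_px_x, geom.deg_per_px_y)
    best_rot = 0.0
    for _ in range(max_iter):
        ys, xs = _crop_window((cx, cy), geom, MD_ANNULUS[1] + margin + 0.5,
                              np.shape(axis_deg))
        grid = _PhasorGrid(np.asarray(axis_deg, float)[ys, xs],
                           valid[ys, xs], geom, y0=ys.start, x0=xs.start)
        best = (np.inf, 0.0, 0.0, 0.0)
        for dy, dx in offs:
            md, rot = grid.md_min_rotation((cx + dx, cy + dy),
                                           n_segments=n_segments)
            if np.isfinite(md) and md < best[0] - 1e-15:
                best = (md, dx, dy, rot)
        if not np.isfinite(best[0]):
            return (cx, cy), best_rot
        best_rot = best[3]
        if best[1] == 0.0 and best[2] == 0.0:
            return (cx, cy), best_rot
        cx, cy = cx + best[1], cy + best[2]
    warnings.warn("joint center/rotation search did not converge")
    return (cx, cy), best_rot


def full_correction(dataset, n_annuli: int = N_ANNULI,
                    n_segments: int = N_SEGMENTS, window_px: int = 31,
                    offset_range: float = 5.0, offset_step: float = 1.0,
                    ) -> HenleResult:
    """Run the four corrections in order and compute the full MD profile.

    Order: rotation anchor → center refinement → anterior-offset grid
    search → second center refinement; then MD for all annuli.
    ``dataset`` needs attributes ``is_os``, ``reference``,
    ``initial_center`` and ``geom`` (see synthetic.SubjectDataset).
    """
    geom = dataset.geom
    comp0 = compensate_anterior(dataset.is_os, dataset.reference)
    axis0 = axis_from_stokes(comp0)
    valid0 = comp0.valid
    # Corrections 1+2: the rotation anchor depends on where the annulus is
    # centered and vice versa, so alternate the two until the center is a
    # fixed point (the initial fovea guess can be ~1° off).
    c1 = tuple(map(float, dataset.initial_center))
    rot = 0.0
    stage1_md = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for _ in range(5):
            axis1, rot = rotation_correction(axis0, valid0, c1, geom,
                                             n_segments)
            c_new, stage1_md = refine_center(axis1, valid0, c1, geom,
                                             window_px, n_segments=n_segments)
            moved = np.hypot(c_new[0] - c1[0], c_new[1] - c1[1])
            c1 = c_new
            if moved < 0.5:
                break
    if not np.isfinite(stage1_md) or stage1_md > 0.8:
        # The sequential scheme can stall when the rotation estimated at a
        # badly displaced center is itself unusable.  Fall back to a joint
        # search: every center candidate is scored by its best-rotation MD.
        c1, rot = _joint_center_rotation(axis0, valid0,
                                         dataset.initial_center, geom,
                                         window_px, n_segments)
        axis1 = np.where(np.isfinite(axis0), wrap_axis(axis0 + rot), np.nan)
    # Corrections 3+4: anterior-compensation offsets (rotation re-fit per
    # candidate, since an axis offset shifts the apparent rotation too),
    # then the fovea position once more on the recompensated map.  A
    # center found under a miscompensated map can be several pixels off
    # and bias the offset argmin, so the pair is iterated to a joint
    # fixed point.
    c2 = c1
    prev_offsets = None
    for _ in range(3):
        offsets, _, rot = offset_search(dataset.is_os, dataset.reference,
                                        None, c2, geom, offset_range,
                                        offset_step, n_segments)
        comp = compensate_anterior(dataset.is_os, dataset.reference, offsets)
        axis2 = axis_from_stokes(comp)
        axis2 = np.where(np.isfinite(axis2), wrap_axis(axis2 + rot), np.nan)
        c_new, _ = refine_center(axis2, comp.valid, c2, geom, window_px,
                                 n_segments=n_segments)
        moved = np.hypot(c_new[0] - c2[0], c_new[1] - c2[1])
        c2 = c_new
        if offsets == prev_offsets and moved < 0.5:
            break
        prev_offsets = offsets
    md = md_profile(axis2, comp.valid, c2, geom, n_annuli, n_segments)
    profile = HenleMDProfile(md, tuple(c2), float(rot),
                             (float(offsets[0]), float(offsets[1])))
    maps = PolarizationMaps(retardation_from_stokes(comp), axis2, comp.valid)
    return HenleResult(profile, maps, comp)


def hfl_extension(profile, cutoff: float = MD_CUTOFF):
    """Lateral HFL extension: where the MD curve crosses the cut-off.

    Scanning outward from the minimum-MD annulus, the first crossing of
    MD above ``cutoff`` is located and its eccentricity is linearly
    interpolated between the mid-radii of the bracketing annuli.
    Returns (extension_deg, flag) with flag one of ``"ok"``,
    ``"no_pattern"`` (MD everywhere above cut-off → 0°) and
    ``"beyond_field"`` (never above cut-off → the 14° field limit).
    """
    md = profile.md if isinstance(profile, HenleMDProfile) else np.asarray(profile, float)
    finite = np.flatnonzero(np.isfinite(md))
    if finite.size < 2:
        raise ValueError("need at least two defined annuli")
    i0 = finite[np.argmin(md[finite])]
    if md[i0] > cutoff:
        return 0.0, "no_pattern"
    prev = i0
    for i in finite[finite > i0]:
        if md[i] > cutoff:
            m_lo, m_hi = prev + 0.5, i + 0.5
            frac = (cutoff - md[prev]) / (md[i] - md[prev])
            return float(m_lo + frac * (m_hi - m_lo)), "ok"
        prev = i
    return float(len(md)), "beyond_field"


def select_best_repeat(profiles: Sequence[HenleMDProfile]) -> int:
    """Index of the repeat with the lowest mean MD over 1–8° eccentricity.

    Annuli 1–2° … 7–8° (indices 1..7) enter the mean; undefined annuli
    are ignored.  Ties go to the first repeat.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    scores = []
    for p in profiles:
        md = p.md if isinstance(p, HenleMDProfile) else np.asarray(p, float)
        seg = md[1:8]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scores.append(np.nanmean(seg))
    scores = [np.inf if not np.isfinite(s) else s for s in scores]
    return int(np.argmin(scores))
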