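"""Stokes-vector polarization mathematics.

The PS-OCT instrument modelled here illuminates the eye with a single
circularly polarized input state and records, per pixel, a Stokes vector
(I, Q, U, V).  We work in the measurement frame in which the *unperturbed*
input state lies along +Q, so that a linear retarder with single-pass
retardation δ and axis orientation θ moves the state on the Poincaré
sphere by an angle 2δ about the equatorial axis (0, cos 2θ, sin 2θ).
In that frame the retrieval formulas are

    δ = ½ · arccos(⟨Q/I⟩_N)        (retardation, [0°, 90°])
    θ = ½ · atan2(⟨U/I⟩_N, −⟨V/I⟩_N)   (axis, [−90°, 90°))

where (⟨Q/I⟩_N, ⟨U/I⟩_N, ⟨V/I⟩_N) is the unit-normalized mean Stokes
direction.  Averaging is always performed on the Stokes components, never
on retardation values: retardation is positive by construction and naive
averaging of noisy retardation maps produces an artificial positive offset.

Retardations are single-pass-equivalent degrees throughout; 9° at 860 nm
corresponds to 21.5 nm of retardance (δ/360·λ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "StokesMap",
    "PolarizationMaps",
    "Retarder",
    "wrap_axis",
    "average_stokes",
    "retardation_from_stokes",
    "axis_from_stokes",
    "polarization_maps",
    "dopu",
    "apply_retarder",
    "estimate_anterior_retarder",
    "compensate_anterior",
    "retardation_deg_to_nm",
]

_EPS = 1e-12


def wrap_axis(theta_deg):
    """Wrap axis-orientation values to the half-turn range [−90°, 90°)."""
    return (np.asarray(theta_deg, dtype=float) + 90.0) % 180.0 - 90.0


@dataclass
class StokesMap:
    """En-face grid of Stokes vectors at a named retinal surface."""

    i: np.ndarray
    q: np.ndarray
    u: np.ndarray
    v: np.ndarray
    surface: str = ""
    valid: Optional[np.ndarray] = None

    def __post_init__(self):
        self.i = np.asarray(self.i, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        for c in (self.q, self.u, self.v):
            if c.shape != self.i.shape:
                raise ValueError("Stokes components must share one shape")
        if self.valid is None:
            self.valid = np.ones(self.i.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.i.shape:
                raise ValueError("valid mask must match component shape")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.i.shape

    def crop(self, ys: slice, xs: slice) -> "StokesMap":
        return StokesMap(self.i[ys, xs], self.q[ys, xs], self.u[ys, xs],
                         self.v[ys, xs], self.surface, self.valid[ys, xs])


@dataclass
class PolarizationMaps:
    """Paired retardation (deg, [0, 90]) and axis (deg, [−90, 90)) maps."""

    retardation: np.ndarray
    axis: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class Retarder:
    """Linear retarder: single-pass retardation and axis orientation, deg."""

    retardation: float
    axis: float

    def __post_init__(self):
        if not (0.0 <= self.retardation < 180.0):
            raise ValueError("retardation must lie in [0°, 180°)")
        if not (-90.0 <= self.axis < 90.0):
            raise ValueError("axis must lie in [−90°, 90°)")


def _normalized_direction(s: StokesMap):
    """Unit Stokes direction (q̂, û, v̂) and a mask where it is defined."""
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(s.i > 0, s.q / s.i, 0.0)
        u = np.where(s.i > 0, s.u / s.i, 0.0)
        v = np.where(s.i > 0, s.v / s.i, 0.0)
    norm = np.sqrt(q * q + u * u + v * v)
    ok = s.valid & (s.i > 0) & (norm > _EPS)
    norm = np.where(norm > _EPS, norm, 1.0)
    return q / norm, u / norm, v / norm, ok


def retardation_from_stokes(s: StokesMap) -> np.ndarray:
    """Retardation δ = ½·arccos(q̂) in degrees; NaN where undefined."""
    qn, _, _, ok = _normalized_direction(s)
    delta = 0.5 * np.degrees(np.arccos(np.clip(qn, -1.0, 1.0)))
    return np.where(ok, delta, np.nan)


def axis_from_stokes(s: StokesMap) -> np.ndarray:
    """Axis orientation θ = ½·atan2(û, −v̂) in [−90°, 90°); NaN where undefined.

    The axis is undefined where the transverse (U, V) component vanishes,
    i.e. at zero (or 90°) retardation.
    """
    _, un, vn, ok = _normalized_direction(s)
    ok = ok & (np.hypot(un, vn) > 1e-9)
    theta = wrap_axis(0.5 * np.degrees(np.arctan2(un, -vn)))
    return np.where(ok, theta, np.nan)


def polarization_maps(s: StokesMap) -> PolarizationMaps:
    ret = retardation_from_stokes(s)
    ax = axis_from_stokes(s)
    return PolarizationMaps(ret, ax, np.isfinite(ret))


def _masked_window_mean(arr, valid, kernel):
    """Mean over a rectangular window, counting only valid pixels.

    Border windows are cropped at the image edge (no padding is invented).
    """
    arr = np.where(valid, arr, 0.0)
    w = np.asarray(valid, dtype=float)
    ksum = ndimage.uniform_filter(arr, size=kernel, mode="constant", cval=0.0)
    wsum = ndimage.uniform_filter(w, size=kernel, mode="constant", cval=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = ksum / wsum
    return out, wsum > _EPS


def average_stokes(s: StokesMap, kernel=None, index_set=None) -> StokesMap:
    """Componentwise Stokes averaging over a window or an index set.

    With ``kernel=(h, w)``, every component is replaced by its windowed
    mean over valid pixels (cropped at the border).  With ``index_set``
    (a boolean mask or integer index arrays), a single averaged Stokes
    pixel is returned as a 1×1 map; an empty valid set yields an invalid
    pixel, not an exception.
    """
    if (kernel is None) == (index_set is None):
        raise ValueError("pass exactly one of kernel / index_set")
    if kernel is not None:
        comps = []
        for c in (s.i, s.q, s.u, s.v):
            m, ok = _masked_window_mean(c, s.valid, kernel)
            comps.append(np.where(ok, m, 0.0))
        return StokesMap(*comps, surface=s.surface, valid=ok)
    sel = index_set
    if getattr(sel, "dtype", None) == bool:
        sel = sel & s.valid
        n = int(sel.sum())
        picker = lambda c: c[sel]
    else:
        v = s.valid[sel]
        n = int(np.count_nonzero(v))
        picker = lambda c: c[sel][v]
    if n == 0:
        z = np.zeros((1, 1))
        return StokesMap(z, z, z, z, surface=s.surface, valid=np.zeros((1, 1), bool))
    vals = [np.array([[picker(c).mean()]]) for c in (s.i, s.q, s.u, s.v)]
    return StokesMap(*vals, surface=s.surface, valid=np.ones((1, 1), bool))


def dopu(s: StokesMap, kernel=(10, 10)) -> np.ndarray:
    """Degree of polarization uniformity over a spatial kernel.

    DOPU is the length of the kernel-mean of per-pixel unit Stokes
    directions: 1 for a spatially uniform state, → 0 for isotropically
    random states.  Border kernels are cropped; NaN where the kernel
    contains no valid pixel.
    """
    qn, un, vn, ok = _normalized_direction(s)
    mq, has = _masked_window_mean(qn, ok, kernel)
    mu, _ = _masked_window_mean(un, ok, kernel)
    mv, _ = _masked_window_mean(vn, ok, kernel)
    d = np.sqrt(mq * mq + mu * mu + mv * mv)
    d = np.clip(d, 0.0, 1.0)
    return np.where(has, d, np.nan)


def _rotate_quv(q, u, v, retardation_deg, axis_deg, inverse=False):
    """Poincaré-sphere rotation by 2δ about the axis (0, cos 2θ, sin 2θ).

    ``retardation_deg`` and ``axis_deg`` may be scalars or per-pixel maps.
    The rotation preserves I and the polarized magnitude ‖(Q,U,V)‖.
    """
    ang = np.deg2rad(2.0 * np.asarray(retardation_deg, dtype=float))
    if inverse:
        ang = -ang
    t2 = np.deg2rad(2.0 * np.asarray(axis_deg, dtype=float))
    au, av = np.cos(t2), np.sin(t2)
    c, sn = np.cos(ang), np.sin(ang)
    ad = au * u + av * v
    q2 = q * c + (au * v - av * u) * sn
    u2 = u * c + (av * q) * sn + au * ad * (1.0 - c)
    v2 = v * c + (-au * q) * sn + av * ad * (1.0 - c)
    return q2, u2, v2


def apply_retarder(s: StokesMap, r: Retarder, inverse: bool = False) -> StokesMap:
    """Transform a Stokes map by a (uniform) linear retarder."""
    q, u, v = _rotate_quv(s.q, s.u, s.v, r.retardation, r.axis, inverse=inverse)
    return StokesMap(s.i.copy(), q, u, v, surface=s.surface, valid=s.valid.copy())


def estimate_anterior_retarder(reference: StokesMap):
    """Per-pixel anterior retarder (δ_a, θ_a) from a reference-surface map.

    Under the known circular input the reference state directly encodes
    the accumulated anterior retardation and axis.  Where the anterior
    retardation is ~0 the axis is unobservable and set to 0 (the
    compensation is then the identity, as it should be).
    Returns (delta_deg, theta_deg, ok_mask).
    """
    delta = retardation_from_stokes(reference)
    theta = axis_from_stokes(reference)
    ok = np.isfinite(delta)
    theta = np.where(np.isfinite(theta), theta, 0.0)
    delta = np.where(ok, delta, 0.0)
    return delta, theta, ok


def compensate_anterior(target: StokesMap, reference: StokesMap,
                        offsets: Tuple[float, float] = (0.0, 0.0)) -> StokesMap:
    """Undo anterior-segment birefringence using a reference-surface map.

    The anterior retarder is estimated per pixel from the reference map,
    optionally perturbed by ``offsets = (dδ, dθ)`` in degrees, and its
    inverse rotation is applied to the target.  With an exact reference
    and zero offsets the sample polarization state is recovered.  Pixels
    with an invalid reference become invalid in the output.
    """
    if reference.shape != target.shape:
        raise ValueError("target and reference must share one grid")
    d_delta, d_theta = offsets
    delta, theta, ok = estimate_anterior_retarder(reference)
    q, u, v = _rotate_quv(target.q, target.u, target.v,
                          delta + d_delta, theta + d_theta, inverse=True)
    return StokesMap(target.i.copy(), q, u, v, surface=target.surface,
                     valid=target.valid & ok)


def retardation_deg_to_nm(delta_deg, wavelength_nm: float = 860.0):
    """Convert retardation from degrees of phase to nm of retardance."""
    delta_deg = np.asarray(delta_deg, dtype=float)
    if np.any(delta_deg < 0):
        raise ValueError("retardation must be non-negative")
    out = delta_deg / 360.0 * wavelength_nm
    return float(out) if out.ndim == 0 else out
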