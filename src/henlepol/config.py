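"""Scan geometry and run configuration.

The scan geometry mirrors a macular PS-OCT raster: a 28° (x) by 21° (y)
field sampled with 1024 A-scans per B-scan and 250 B-scans, recorded at a
center wavelength of 860 nm.  On a standard eye 28° corresponds to ~8 mm,
hence the default ``mm_per_deg`` of 8/28.

Pixels are anisotropic: 1024/28 ≈ 36.6 px/deg along x but 250/21 ≈ 11.9
px/deg along y.  Every eccentricity or azimuth computation therefore runs
in degree space, never in pixel space; :meth:`SceneGeometry.polar_deg` is
the single place that conversion happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
import yaml


@dataclass(frozen=True)
class SceneGeometry:
    """En-face scan geometry (field of view, sampling, optics)."""

    field_deg: Tuple[float, float] = (28.0, 21.0)
    grid_px: Tuple[int, int] = (1024, 250)  # (nx, ny)
    mm_per_deg: float = 8.0 / 28.0
    wavelength_nm: float = 860.0

    @property
    def deg_per_px_x(self) -> float:
        return self.field_deg[0] / self.grid_px[0]

    @property
    def deg_per_px_y(self) -> float:
        return self.field_deg[1] / self.grid_px[1]

    @property
    def shape(self) -> Tuple[int, int]:
        """Array shape (ny, nx) of en-face maps on this grid."""
        return (self.grid_px[1], self.grid_px[0])

    def center_px(self) -> Tuple[float, float]:
        return ((self.grid_px[0] - 1) / 2.0, (self.grid_px[1] - 1) / 2.0)

    def offsets_deg(self, center_xy, *, y0: int = 0, x0: int = 0, shape=None):
        """Signed offsets (dx, dy_up) in degrees from ``center_xy`` (px).

        ``dy_up`` is positive toward the top of the image (decreasing row
        index), matching the azimuth convention with φ = 0 at the upward
        vertical.  ``y0``/``x0``/``shape`` address a sub-window of the grid.
        """
        cx, cy = center_xy
        ny, nx = shape if shape is not None else self.shape
        xs = (np.arange(x0, x0 + nx) - cx) * self.deg_per_px_x
        ys = (cy - np.arange(y0, y0 + ny)) * self.deg_per_px_y
        return np.meshgrid(xs, ys)

    def polar_deg(self, center_xy, *, y0: int = 0, x0: int = 0, shape=None):
        """Eccentricity (deg) and azimuth φ ∈ [0°, 360°) about a center.

        φ = 0 at the upward vertical from the center, increasing
        counterclockwise (toward the left of the image).
        """
        dx, dy = self.offsets_deg(center_xy, y0=y0, x0=x0, shape=shape)
        ecc = np.hypot(dx, dy)
        phi = np.degrees(np.arctan2(-dx, dy)) % 360.0
        return ecc, phi


def eccentricity_to_area_mm2(ecc_deg: float, geom: SceneGeometry | None = None) -> float:
    """Retinal area (mm²) of a disc of the given angular radius.

    A 5° radius maps to 6.4 mm² and 12° to 36.9 mm² under the default
    28° ↔ 8 mm geometry.
    """
    if geom is None:
        geom = SceneGeometry()
    r_mm = ecc_deg * geom.mm_per_deg
    return float(np.pi * r_mm**2)


@dataclass
class RunConfig:
    """All tunable analysis parameters, defaulting to the published values.

    Defaults: 14 one-degree annuli of 360 one-degree segments, MD cut-off
    0.65, 31×31 px fovea-refinement window, ±5° offset grid in 1° steps,
    10×10 px DOPU kernel, 9×9 px Stokes smoothing, 5-px depth band,
    DOPU cut 0.75 and ±8 px search window for the IS/OS refinement.
    """

    geometry: SceneGeometry = field(default_factory=SceneGeometry)
    n_annuli: int = 14
    n_segments: int = 360
    md_cutoff: float = 0.65
    center_window_px: int = 31
    offset_range_deg: float = 5.0
    offset_step_deg: float = 1.0
    dopu_kernel: Tuple[int, int] = (10, 10)
    dopu_cut: float = 0.75
    isos_halfwidth_px: int = 8
    smooth_kernel: Tuple[int, int] = (9, 9)
    depth_band_px: int = 5
    profile_bin_deg: float = 0.25
    welch: bool = False
    bonferroni: bool = False
    # cohort simulation
    n_healthy: int = 20
    n_glaucoma: int = 20
    n_repeats: int = 1
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        geom = d.pop("geometry", None)
        known = {f for f in cls.__dataclass_fields__ if f != "geometry"}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**{k: _coerce(k, v) for k, v in d.items()})
        if geom is not None:
            try:
                geom = {k: tuple(v) if isinstance(v, list) else v for k, v in geom.items()}
                cfg.geometry = SceneGeometry(**geom)
            except TypeError as exc:
                raise ConfigError(f"bad geometry block: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_annuli < 1 or self.n_segments < 4:
            raise ConfigError("need at least one annulus and four segments")
        if not (0 < self.md_cutoff):
            raise ConfigError("md_cutoff must be positive")
        if self.center_window_px % 2 != 1:
            raise ConfigError("center_window_px must be odd")
        if self.offset_step_deg <= 0 or self.offset_range_deg < 0:
            raise ConfigError("offset grid must have positive step")
        if self.depth_band_px < 1:
            raise ConfigError("depth_band_px must be >= 1")


def _coerce(key, value):
    if isinstance(value, list):
        return tuple(value)
    return value


class ConfigError(ValueError):
    """Raised for invalid run configurations (CLI exit code 2)."""
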