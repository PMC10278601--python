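"""File formats: multi-page TIFF Stokes maps, JSON ground truth, CSV tables.

Stokes maps are written as 5-page float32 TIFFs (pages I, Q, U, V,
validity mask); ground truth and run metadata as JSON; MD profiles,
retardation profiles and cohort tables as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .polarization import StokesMap
from .synthetic import HenleGroundTruth

STOKES_PAGES = ("I", "Q", "U", "V", "valid")


def write_stokes_tiff(path, s: StokesMap) -> None:
    pages = np.stack([s.i, s.q, s.u, s.v, s.valid.astype(float)])
    tifffile.imwrite(path, pages.astype(np.float32),
                     metadata={"surface": s.surface, "pages": list(STOKES_PAGES)})


def read_stokes_tiff(path, surface: str = "") -> StokesMap:
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 5:
        raise ValueError(f"{path}: expected 5 pages (I,Q,U,V,valid)")
    i, q, u, v, m = (np.asarray(p, dtype=float) for p in pages)
    return StokesMap(i, q, u, v, surface=surface, valid=m > 0.5)


def write_truth_json(path, truth: HenleGroundTruth, extra: dict | None = None) -> None:
    d = dataclasses.asdict(truth)
    d["fovea_center"] = list(d["fovea_center"])
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(_jsonable(d), indent=2))


def read_truth_json(path):
    d = json.loads(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(HenleGroundTruth)}
    extra = {k: v for k, v in d.items() if k not in fields}
    kw = {k: v for k, v in d.items() if k in fields}
    kw["fovea_center"] = tuple(kw["fovea_center"])
    if np.isinf(np.float64(kw.get("snr_db", 0.0))):
        kw["snr_db"] = np.inf
    return HenleGroundTruth(**kw), extra


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return "inf" if np.isinf(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_md_profile_csv(path, profile) -> None:
    """MD-per-annulus table; one row per annulus with its radius bounds."""
    md = np.asarray(profile.md, dtype=float)
    df = pd.DataFrame({
        "annulus_inner_deg": np.arange(len(md)),
        "annulus_outer_deg": np.arange(len(md)) + 1,
        "md": md,
    })
    df.attrs["center_used"] = profile.center_used
    df.to_csv(path, index=False)


def write_retardation_profile_csv(path, profile) -> None:
    pd.DataFrame({
        "eccentricity_deg": profile.eccentricity,
        "retardation_deg": profile.retardation,
        "n_pixels": profile.counts,
    }).to_csv(path, index=False)
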