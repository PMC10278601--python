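"""Group-level statistics for cohort comparison.

Two-sided Student's t-tests (equal-variance by default, Welch as an
option), Tukey-style box-plot summaries with the 1.5·IQR outlier rule,
ordinary-least-squares regression of measured HFL extension on SNR, and
test–retest repeatability (per-subject SD of repeated extensions).

Raw p-values are reported for the seven per-annulus comparisons; a
Bonferroni option exists but is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SubjectRecord", "BoxplotSummary", "two_sample_t",
           "boxplot_summary", "snr_extension_regression", "repeatability",
           "annulus_comparison", "records_to_frame"]

log = logging.getLogger(__name__)

GROUPS = ("healthy", "glaucoma")


@dataclass
class SubjectRecord:
    """One row of the cohort table."""

    id: str
    group: str
    age: float
    snr: float
    extension: float            # deg
    extension_flag: str = "ok"
    peak: float = np.nan        # deg
    peak_ecc: float = np.nan    # deg
    auc_1_8: float = np.nan     # deg·deg
    annulus_means: Sequence[float] = field(default_factory=lambda: [np.nan] * 7)
    repeat_sd: Optional[float] = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if not (0.0 <= self.extension <= 14.0):
            raise ValueError("extension must lie in [0°, 14°]")


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"id": r.id, "group": r.group, "age": r.age, "snr": r.snr,
               "extension": r.extension, "extension_flag": r.extension_flag,
               "peak": r.peak, "peak_ecc": r.peak_ecc, "auc_1_8": r.auc_1_8,
               "repeat_sd": r.repeat_sd}
        for k, m in enumerate(r.annulus_means):
            row[f"ret_{k + 1}_{k + 2}deg"] = m
        rows.append(row)
    return pd.DataFrame(rows)


def two_sample_t(a, b, equal_var: bool = True) -> Tuple[float, float]:
    """Two-sided two-sample t-test; Student (pooled variance) by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n ≥ 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("t-test undefined: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BoxplotSummary:
    p25: float
    median: float
    p75: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray


def boxplot_summary(values) -> BoxplotSummary:
    """Quartiles (linear-interpolation percentiles) and 1.5·IQR outliers.

    Outliers are points above P75 + 1.5·(P75−P25) or below
    P25 − 1.5·(P75−P25); whiskers reach the most extreme non-outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    p25, med, p75 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = p75 - p25
    lo_fence, hi_fence = p25 - 1.5 * iqr, p75 + 1.5 * iqr
    inside = (v >= lo_fence) & (v <= hi_fence)
    outliers = np.sort(v[~inside])
    return BoxplotSummary(float(p25), float(med), float(p75),
                          float(v[inside].min()), float(v[inside].max()),
                          outliers)


def snr_extension_regression(records) -> Tuple[float, float]:
    """OLS slope of HFL extension on SNR with its two-sided p-value.

    ``records`` is either a sequence of SubjectRecord or a pair of
    arrays (snr, extension).
    """
    if isinstance(records, tuple) and len(records) == 2:
        snr, ext = (np.asarray(x, dtype=float) for x in records)
    else:
        snr = np.array([r.snr for r in records], dtype=float)
        ext = np.array([r.extension for r in records], dtype=float)
    if snr.size < 3:
        raise ValueError("regression needs n ≥ 3")
    if np.ptp(snr) == 0:
        raise ValueError("slope undefined: constant SNR")
    res = stats.linregress(snr, ext)
    return float(res.slope), float(res.pvalue)


def repeatability(repeats: Dict[str, Sequence[float]]):
    """Per-subject sample SD of repeated extension measurements.

    Subjects with fewer than two repeats are skipped (and logged).
    Returns (per-subject dict of SDs, cohort mean SD).
    """
    out: Dict[str, float] = {}
    for sid, vals in repeats.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            log.warning("subject %s has <2 repeats; skipped", sid)
            continue
        out[sid] = float(np.std(vals, ddof=1))
    if not out:
        raise ValueError("no subject has ≥2 repeats")
    return out, float(np.mean(list(out.values())))


def annulus_comparison(frame: pd.DataFrame, equal_var: bool = True,
                       bonferroni: bool = False) -> pd.DataFrame:
    """Per-annulus healthy-vs-glaucoma t-tests on mean retardation."""
    cols = [c for c in frame.columns if c.startswith("ret_")]
    h = frame[frame.group == "healthy"]
    g = frame[frame.group == "glaucoma"]
    rows = []
    for c in cols:
        a, b = h[c].dropna(), g[c].dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append({"annulus": c, "t": np.nan, "p": np.nan})
            continue
        t, p = two_sample_t(a, b, equal_var=equal_var)
        if bonferroni:
            p = min(1.0, p * len(cols))
        rows.append({"annulus": c, "t": t, "p": p,
                     "mean_healthy": a.mean(), "mean_glaucoma": b.mean()})
    return pd.DataFrame(rows)
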