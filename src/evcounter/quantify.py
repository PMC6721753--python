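"""Count statistics: volume extrapolation, ratios, replicate variability,
box-plot summaries and correlation against reference counts.

A whole-blood well represents 0.02 uL of undiluted blood at the default
geometry; counts are extrapolated linearly to 1 uL or 7.5 mL.  Replicate
variability is summarized as the percent standard error of the mean over
4-6 technical replicates.  Box-plot whiskers follow the Q1 - 1.5*IQR /
Q3 + 1.5*IQR convention with linear-interpolation quartiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

UL_PER_7P5_ML = 7500.0


@dataclass
class WellResult:
    """Per-class counts for one imaged well plus volume metadata."""

    well_id: str
    donor_id: str
    mode: str
    counts: dict[str, int]
    sampled_volume_ul: float

    def __post_init__(self) -> None:
        if self.sampled_volume_ul <= 0:
            raise ValueError("sampled_volume_ul must be > 0")
        for cls, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {cls!r}")


@dataclass
class ReplicateStats:
    mean: float
    sd: float
    se_pct: float     # nan when mean == 0
    n: int


@dataclass
class BoxplotStats:
    q1: float
    median: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    n: int


@dataclass
class CorrelationFit:
    slope: float
    intercept: float
    r_squared: float
    n: int
    underestimation_factor: float = math.nan   # mean(imaging) / mean(reference)


def extrapolate(count: float, sampled_volume_ul: float,
                target_volume_ul: float) -> float:
    """Linearly extrapolate a count to a target blood volume (a rate,
    not rounded)."""
    if sampled_volume_ul <= 0:
        raise ValueError("sampled_volume_ul must be > 0")
    return count * target_volume_ul / sampled_volume_ul


def relative_frequency(counts: Mapping[str, float]) -> float:
    """Leukocytes per ldEV (e.g. 3.0 means one ldEV per three leukocytes).

    Undefined (NaN) when the ldEV count is zero.
    """
    ldev = counts.get("ldEV", 0)
    if ldev == 0:
        return math.nan
    return counts.get("leukocyte", 0) / ldev


def replicate_stats(values: Sequence[float]) -> ReplicateStats:
    """Mean, sample SD (n-1) and percent standard error over replicates."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("replicate_stats needs at least 2 replicates")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    se_pct = 100.0 * (sd / math.sqrt(n)) / mean if mean > 0 else math.nan
    return ReplicateStats(mean, sd, se_pct, n)


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    """Quartiles (linear interpolation) and 1.5*IQR whiskers."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    return BoxplotStats(float(q1), float(med), float(q3), float(iqr),
                        float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr),
                        int(values.size))


def correlate(imaging: Sequence[float], reference: Sequence[float]) -> CorrelationFit:
    """Ordinary least-squares fit of reference on imaging counts.

    ``r_squared = 1 - SSres/SStot``; requires >= 3 pairs and non-constant
    values on both axes.
    """
    x = np.asarray(imaging, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.size != y.size:
        raise ValueError("imaging and reference must be paired")
    if x.size < 3:
        raise ValueError("correlate needs at least 3 paired observations")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("degenerate fit: zero variance in inputs")
    fit = stats.linregress(x, y)
    under = float(x.mean() / y.mean()) if y.mean() != 0 else math.nan
    return CorrelationFit(float(fit.slope), float(fit.intercept),
                          float(fit.rvalue ** 2), int(x.size), under)


# ---------------------------------------------------------------------------
# Cohort-level tables

def summarize_donors(wells: Sequence[WellResult],
                     classes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-donor, per-class replicate statistics and extrapolations.

    One row per (donor, class): replicate mean/SD/SE%, counts per uL and
    per 7.5 mL, and the donor's ldEV-per-leukocyte ratio (from replicate
    means).
    """
    if classes is None:
        seen: dict[str, None] = {}
        for w in wells:
            for cls in w.counts:
                if cls not in ("unclassified", "ambiguous"):
                    seen.setdefault(cls)
        classes = list(seen)
    rows = []
    donors: dict[str, list[WellResult]] = {}
    for w in wells:
        donors.setdefault(w.donor_id, []).append(w)
    for donor_id, dw in donors.items():
        vol = dw[0].sampled_volume_ul
        means = {}
        for cls in classes:
            vals = [w.counts.get(cls, 0) for w in dw]
            st = replicate_stats(vals) if len(vals) >= 2 else ReplicateStats(
                float(vals[0]), math.nan, math.nan, 1)
            means[cls] = st.mean
            rows.append({
                "donor_id": donor_id, "class": cls, "n_wells": st.n,
                "mean_per_well": st.mean, "sd_per_well": st.sd,
                "se_pct": st.se_pct,
                "per_ul": extrapolate(st.mean, vol, 1.0),
                "per_7p5ml": extrapolate(st.mean, vol, UL_PER_7P5_ML),
            })
        leuk = means.get("leukocyte", 0.0)
        ldev = means.get("ldEV", 0.0)
        ratio = ldev / leuk if leuk > 0 else math.nan
        for r in rows:
            if r["donor_id"] == donor_id:
                r.setdefault("ldev_per_leukocyte", ratio)
    return pd.DataFrame(rows)


def summarize_cohort(donor_summary: pd.DataFrame, group: str = "cohort",
                     value_col: str = "per_7p5ml") -> pd.DataFrame:
    """Cohort box-plot statistics per class over per-donor values, plus the
    pooled leukocytes-per-ldEV ratio."""
    rows = []
    pooled = donor_summary.groupby("class")["mean_per_well"].sum()
    ratio = relative_frequency(pooled.to_dict())
    for cls, sub in donor_summary.groupby("class"):
        bs = boxplot_stats(sub[value_col].to_numpy())
        rows.append({
            "group": group, "class": cls, "n_donors": bs.n,
            "q1": bs.q1, "median": bs.median, "q3": bs.q3, "iqr": bs.iqr,
            "whisker_low": bs.whisker_low, "whisker_high": bs.whisker_high,
            "leukocytes_per_ldev": ratio,
        })
    return pd.DataFrame(rows)


def correlation_report(donor_summary: pd.DataFrame,
                       reference: pd.DataFrame) -> dict[str, CorrelationFit]:
    """Correlate per-donor imaging counts (per uL) with reference counts.

    ``reference`` needs columns ``donor_id``, ``class``, ``per_ul``.
    Per-donor replicate means are correlated class by class.
    """
    out = {}
    merged = donor_summary.merge(reference, on=["donor_id", "class"],
                                 suffixes=("_imaging", "_reference"))
    for cls, sub in merged.groupby("class"):
        out[cls] = correlate(sub["per_ul_imaging"].to_numpy(),
                             sub["per_ul_reference"].to_numpy())
    return out
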