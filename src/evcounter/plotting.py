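"""Static figures: cohort box plots and imaging-vs-reference scatter."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def cohort_boxplot(cohort_summary: pd.DataFrame, ax=None,
                   value_label: str = "objects per 7.5 mL"):
    """Box plot per class from precomputed quartile/whisker statistics."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    stats = []
    for _, row in cohort_summary.iterrows():
        stats.append({
            "label": row["class"], "med": row["median"],
            "q1": row["q1"], "q3": row["q3"],
            "whislo": row["whisker_low"], "whishi": row["whisker_high"],
            "fliers": [],
        })
    ax.bxp(stats, showfliers=False)
    ax.set_yscale("log")
    ax.set_ylabel(value_label)
    return ax


def correlation_scatter(imaging, reference, fit=None, ax=None,
                        class_name: str = ""):
    """Scatter of imaging-derived vs reference per-uL counts with OLS line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(imaging, reference, s=20, color="k")
    if fit is not None:
        xs = [min(imaging), max(imaging)]
        ax.plot(xs, [fit.slope * x + fit.intercept for x in xs], "b-")
        ax.set_title(f"{class_name} R$^2$ = {fit.r_squared:.2f}".strip())
    ax.set_xlabel("fluorescence imaging (per uL)")
    ax.set_ylabel("reference (per uL)")
    return ax
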