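"""Cross-readout statistics: Pearson correlations of MRI volume against
post-mortem readouts, one-way ANOVA with Bonferroni-adjusted pairwise
comparisons, and baseline subtraction of longitudinal MRI volumes.

Missing readouts are handled by pairwise-complete deletion, and the number
of complete pairs is reported per correlation so that readouts measured on
subsets of the cohort (e.g. histology on half the animals) are transparent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson",
    "AnovaResult",
    "anova_bonferroni",
    "baseline_subtract",
    "correlation_report",
    "format_p",
]

#: p-values below this are reported as "< 1e-15" rather than 0.
P_FLOOR = 1e-15


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson R with a two-sided t-based p-value
    (t = R·sqrt((n−2)/(1−R²)) on n−2 degrees of freedom).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D")
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA with Bonferroni pairwise t-tests."""

    f_statistic: float
    p_value: float
    groups: tuple[str, ...]
    pairwise: pd.DataFrame  # group1, group2, t, p_raw, p_bonferroni


def anova_bonferroni(table: pd.DataFrame,
                     readout: str,
                     group_col: str = "group",
                     groups: list[str] | None = None) -> AnovaResult:
    """One-way ANOVA over ``groups`` on ``readout``, plus all pairwise
    pooled-variance t-tests with Bonferroni-adjusted p-values (raw p times
    the number of comparisons, capped at 1)."""
    if readout not in table or group_col not in table:
        raise ValueError(f"missing column {readout!r} or {group_col!r}")
    data = table[[group_col, readout]].dropna()
    labels = groups or sorted(data[group_col].unique())
    samples = []
    for g in labels:
        vals = data.loc[data[group_col] == g, readout].to_numpy(float)
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        samples.append(vals)
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    f, p = stats.f_oneway(*samples)
    n_comp = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            t, praw = stats.ttest_ind(samples[i], samples[j], equal_var=True)
            rows.append((labels[i], labels[j], float(t), float(praw),
                         min(1.0, float(praw) * n_comp)))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "t", "p_raw",
                                           "p_bonferroni"])
    return AnovaResult(f_statistic=float(f), p_value=float(p),
                       groups=tuple(labels), pairwise=pairwise)


def baseline_subtract(table: pd.DataFrame,
                      baseline_timepoint: str = "baseline",
                      timepoint_col: str = "timepoint",
                      animal_col: str = "animal_id",
                      volume_col: str = "mri_volume_ul") -> pd.DataFrame:
    """Add ``injury_volume_ul`` = each row's MRI volume minus the same
    animal's baseline volume (baseline signal contains vessels; the
    difference isolates the injury). Negative differences are reported,
    not clipped."""
    for col in (timepoint_col, animal_col, volume_col):
        if col not in table:
            raise ValueError(f"missing column {col!r}")
    base = table.loc[table[timepoint_col] == baseline_timepoint]
    if base[animal_col].duplicated().any():
        raise ValueError("multiple baseline rows for one animal")
    ref = base.set_index(animal_col)[volume_col]
    missing = set(table[animal_col]) - set(ref.index)
    if missing:
        raise ValueError(f"animals missing a baseline row: {sorted(missing)}")
    out = table.copy()
    out["injury_volume_ul"] = (
        out[volume_col] - out[animal_col].map(ref).to_numpy())
    return out


def correlation_report(table: pd.DataFrame,
                       reference: str = "mri_volume_ul",
                       readouts: list[str] | None = None) -> pd.DataFrame:
    """Correlate every available readout against the reference column.

    Pairwise-complete deletion per readout; rows are ranked by |R|
    descending. Returns columns: readout, n, r, p, p_label.
    """
    if reference not in table:
        raise ValueError(f"missing reference column {reference!r}")
    if readouts is None:
        readouts = [c for c in table.columns
                    if c != reference
                    and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for col in readouts:
        pair = table[[reference, col]].dropna()
        if len(pair) < 3:
            continue
        r, p = pearson(pair[reference], pair[col])
        rows.append((col, len(pair), r, p, format_p(p)))
    if not rows:
        raise ValueError("no readout has >= 3 complete pairs with the "
                         "reference")
    report = pd.DataFrame(rows, columns=["readout", "n", "r", "p", "p_label"])
    return (report.reindex(report["r"].abs()
                           .sort_values(ascending=False).index)
            .reset_index(drop=True))


def format_p(p: float) -> str:
    """Human-readable p-value; values below the representable floor are
    shown as '< 1e-15' rather than 0."""
    if p < P_FLOOR:
        return "< 1e-15"
    return f"{p:.3g}"
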