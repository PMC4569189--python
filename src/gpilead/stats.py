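"""Descriptive and inferential statistics over per-lead records.

Cohort tables report means with sample standard deviations (n-1
denominator), printed to one decimal for mm and years and to whole
percentages for label proportions, rounding half away from zero.  Group
contrasts (dystonia vs Parkinson's disease, atlas vs direct planning)
use the two-sided unpaired pooled-variance t-test after a
Kolmogorov-Smirnov normality check; p < 0.05 is considered significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "InsufficientDataError",
    "round_half_away",
    "describe",
    "GroupComparison",
    "compare_groups",
    "location_label_summary",
]

ALPHA = 0.05


class InsufficientDataError(ValueError):
    """A group contributes fewer than two records."""


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed tables),
    unlike banker's rounding."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def describe(
    records: pd.DataFrame,
    field: str,
    group_by: str | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Mean, sample SD (n-1) and n of ``field``, optionally per group.

    Returns a tidy frame with columns ``group``, ``n``, ``mean``, ``sd``
    plus display-rounded ``mean_disp``/``sd_disp``; full precision is kept
    in ``mean``/``sd``, rounding is presentation only.
    """
    if group_by is None:
        groups = [("all", records)]
    else:
        groups = list(records.groupby(group_by))
    rows = []
    for name, g in groups:
        vals = g[field].astype(float).to_numpy()
        if len(vals) < 2:
            raise InsufficientDataError(
                f"group {name!r} has {len(vals)} record(s); need at least 2"
            )
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        rows.append(
            {
                "group": name,
                "n": len(vals),
                "mean": mean,
                "sd": sd,
                "mean_disp": round_half_away(mean, decimals),
                "sd_disp": round_half_away(sd, decimals),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group contrast with normality metadata."""

    field: str
    groups: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    t_statistic: float
    p_value: float
    test: str
    significant: bool
    ks_p_values: tuple[float, float]
    normality_ok: bool


def compare_groups(
    records: pd.DataFrame, field: str, grouping: str
) -> GroupComparison:
    """Two-sided unpaired pooled-variance t-test between the two groups
    of ``grouping``.

    Normality of each group is pre-checked with a one-sample
    Kolmogorov-Smirnov test against a normal with the group's estimated
    moments; the KS p-values travel with the result as metadata.  A
    degenerate pooled variance yields ``p_value = nan`` with test
    ``"undefined"`` rather than an exception.
    """
    names = sorted(records[grouping].dropna().unique().tolist())
    if len(names) != 2:
        raise ValueError(f"grouping {grouping!r} must define exactly 2 groups, got {names}")
    a = records.loc[records[grouping] == names[0], field].astype(float).to_numpy()
    b = records.loc[records[grouping] == names[1], field].astype(float).to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 records")

    ks = []
    for sample in (a, b):
        sd = np.std(sample, ddof=1)
        if sd == 0:
            ks.append(0.0)
        else:
            ks.append(float(sps.kstest(sample, "norm", args=(np.mean(sample), sd)).pvalue))

    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        t_stat, p = float("nan"), float("nan")
        test = "undefined"
    elif np.array_equal(np.sort(a), np.sort(b)):
        # identical samples: no evidence of a difference
        t_stat, p, test = 0.0, 1.0, "unpaired pooled-variance t-test"
    else:
        t_stat, p = sps.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(t_stat), float(p)
        test = "unpaired pooled-variance t-test"
    return GroupComparison(
        field=field,
        groups=(str(names[0]), str(names[1])),
        n=(len(a), len(b)),
        means=(float(np.mean(a)), float(np.mean(b))),
        sds=(float(np.std(a, ddof=1)), float(np.std(b, ddof=1))),
        t_statistic=t_stat,
        p_value=p,
        test=test,
        significant=bool(p < ALPHA) if not math.isnan(p) else False,
        ks_p_values=(ks[0], ks[1]),
        normality_ok=all(k >= ALPHA for k in ks),
    )


def location_label_summary(
    records: pd.DataFrame, column: str = "active_location"
) -> pd.DataFrame:
    """Counts and integer-rounded percentages of active-contact labels."""
    counts = records[column].value_counts()
    total = int(counts.sum())
    rows = [
        {
            "label": label,
            "count": int(cnt),
            "percent": int(round_half_away(100.0 * cnt / total)),
        }
        for label, cnt in counts.items()
    ]
    return pd.DataFrame(rows).sort_values("count", ascending=False, ignore_index=True)
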