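"""Phytohormone panel statistics: per-analyte fold change and t-test.

Works on a long replicate table (analyte, rt_min, group, replicate,
content in ng/g) with two groups — e.g. a cold-sensitive and a
cold-tolerant genotype after chilling. The report prints the fold change
in both orientations because panel tables in the literature are not
consistent about which genotype is the numerator; the headline ``fc``
column is mean_a / mean_b (first group / second group, in table order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ChillseqError

DEFAULT_ALPHA = 0.05
#: "Two-sample t-test" with no further qualification is read as the
#: pooled-variance Student's t; Welch is available by flag.
DEFAULT_VARIANT = "pooled"


@dataclass
class HormoneResult:
    analyte: str
    rt_min: float
    mean_a: float
    mean_b: float
    fc: float  # mean_a / mean_b
    p: float
    significant: bool


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of group means, numerator/denominator as supplied."""
    if mean_b == 0:
        raise ChillseqError("fold change undefined: denominator mean is zero")
    return mean_a / mean_b


def two_sample_t(reps_a, reps_b, variant: str = DEFAULT_VARIANT) -> float:
    """Two-sided two-sample t-test p-value (pooled or Welch).

    Degenerate case: zero variance in both groups with equal means is a
    perfect null and returns p = 1; zero variance with different means
    returns p = 0 (separation is certain under the model).
    """
    a = np.asarray(reps_a, dtype=float)
    b = np.asarray(reps_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ChillseqError("need at least two replicates per group")
    if variant not in ("pooled", "welch"):
        raise ChillseqError(f"unknown t-test variant {variant!r}")
    # constant replicate vectors: np.ptp is exact where the variance of an
    # unrepresentable mean is not
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.pvalue)


def summarize_panel(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    variant: str = DEFAULT_VARIANT,
) -> pd.DataFrame:
    """One row per analyte: group means, FC (both orientations), p, flag.

    Groups are taken in order of first appearance in the table; analytes
    keep their input order. Raw values are returned at full precision;
    :func:`format_report` applies the conventional 2-decimal FC /
    3-decimal p rounding.
    """
    required = {"analyte", "group", "content"}
    if not required.issubset(table.columns):
        raise ChillseqError(f"hormone table needs columns {sorted(required)}")
    groups = list(dict.fromkeys(table["group"]))
    if len(groups) != 2:
        raise ChillseqError(f"need exactly two groups, got {groups}")
    ga, gb = groups
    rows = []
    for analyte in dict.fromkeys(table["analyte"]):
        sub = table[table["analyte"] == analyte]
        a = sub.loc[sub["group"] == ga, "content"].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == gb, "content"].to_numpy(dtype=float)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        p = two_sample_t(a, b, variant=variant)
        rows.append(
            {
                "analyte": analyte,
                "rt_min": float(sub["rt_min"].iloc[0]) if "rt_min" in sub else np.nan,
                f"mean_{ga}": mean_a,
                f"mean_{gb}": mean_b,
                "fc": fold_change(mean_a, mean_b),
                "fc_reversed": fold_change(mean_b, mean_a),
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def format_report(summary: pd.DataFrame) -> pd.DataFrame:
    """Round FC columns to 2 decimals and p to 3, panel-table style."""
    out = summary.copy()
    for col in ("fc", "fc_reversed"):
        out[col] = out[col].round(2)
    out["p"] = out["p"].round(3)
    return out
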