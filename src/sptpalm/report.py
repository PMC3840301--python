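"""Pooled statistics and two-condition comparison reports.

Per-trajectory diffusion records pooled across acquisitions are summarized
per group (median D with 25th/75th percentiles, group proportions) and
compared between groups or conditions with the two-sample
Kolmogorov-Smirnov test on the full distributions, the standard choice for
skewed single-molecule diffusion-coefficient distributions. Significance is
reported with the usual star convention (* p < 0.05, ** p < 0.01,
*** p < 0.001); no multiple-testing correction is applied (stars are
per-comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "significance_stars",
    "pool_and_summarize",
    "ks_compare",
    "condition_report",
]


@dataclass
class GroupSummary:
    """Pooled statistics of one trajectory group."""

    group: str
    n: int
    median_D_um2s: float
    q25_D_um2s: float
    q75_D_um2s: float
    median_area_per_step_px: float
    fraction_pct: float


@dataclass
class ComparisonResult:
    """Two-sample KS comparison of pooled distributions."""

    group_pair: tuple[str, str]
    statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int


def significance_stars(p: float, thresholds=(0.05, 0.01, 0.001)) -> str:
    """'***', '**', '*' or 'ns' from a p-value (pure function of p)."""
    if p < thresholds[2]:
        return "***"
    if p < thresholds[1]:
        return "**"
    if p < thresholds[0]:
        return "*"
    return "ns"


def pool_and_summarize(records: pd.DataFrame, group_by: str = "cluster_label") -> list[GroupSummary]:
    """Per-group median/quartiles of D, median area per step, and share of total.

    Percentiles use linear interpolation between order statistics. Group
    fractions are percentages of all pooled records, so complementary
    label sets (trapped + free, synaptic + extra-synaptic) sum to 100%.
    """
    if len(records) == 0:
        raise ValueError("no records to summarize")
    if group_by not in records.columns:
        raise ValueError(f"unknown group key {group_by!r}")
    total = len(records)
    out = []
    for group, sub in records.groupby(group_by, sort=True):
        d = sub["D_um2s"].to_numpy()
        q25, q50, q75 = np.percentile(d, [25, 50, 75])
        area = sub["area_per_step_px"].to_numpy()
        area = area[np.isfinite(area)]
        out.append(
            GroupSummary(
                group=str(group),
                n=len(sub),
                median_D_um2s=float(q50),
                q25_D_um2s=float(q25),
                q75_D_um2s=float(q75),
                median_area_per_step_px=float(np.median(area)) if area.size else float("nan"),
                fraction_pct=100.0 * len(sub) / total,
            )
        )
    return out


def ks_compare(sample_a, sample_b, labels: tuple[str, str] = ("a", "b")) -> ComparisonResult:
    """Two-sided two-sample Kolmogorov-Smirnov comparison.

    Exact p-value for small samples (both n <= 25), asymptotic otherwise.
    Samples below n = 5 trigger a statistical-power warning but still
    return a result.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if min(len(a), len(b)) < 5:
        warnings.warn("KS comparison on < 5 observations has little power")
    method = "exact" if max(len(a), len(b)) <= 25 else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        group_pair=labels,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        stars=significance_stars(float(res.pvalue)),
        n_a=len(a),
        n_b=len(b),
    )


def condition_report(
    records_by_condition: dict[str, pd.DataFrame],
    group_by: str = "cluster_label",
    baseline: str | None = None,
) -> pd.DataFrame:
    """Condition-comparison table of median D per group.

    Rows are group labels (e.g. free / trapped), columns conditions; each
    cell reads "median D (n = ...)". Every non-baseline condition carries a
    KS significance marker against the baseline (default: the first
    condition) for that group's D distribution. Empty cells are 'n/a'.
    """
    conditions = list(records_by_condition)
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    if baseline is None:
        baseline = conditions[0]
    groups = sorted(
        {g for df in records_by_condition.values() for g in df[group_by].unique()}
    )
    table = {}
    for cond in conditions:
        col = []
        df = records_by_condition[cond]
        base = records_by_condition[baseline]
        for g in groups:
            d = df.loc[df[group_by] == g, "D_um2s"].to_numpy()
            if d.size == 0:
                col.append("n/a")
                continue
            cell = f"{np.median(d):.4f} (n = {d.size})"
            if cond != baseline:
                d0 = base.loc[base[group_by] == g, "D_um2s"].to_numpy()
                if d0.size:
                    cmp = ks_compare(d0, d, labels=(baseline, cond))
                    cell += f" {cmp.stars}"
            col.append(cell)
        table[cond] = col
    return pd.DataFrame(table, index=pd.Index(groups, name=group_by))
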