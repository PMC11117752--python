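"""Cohort-level aggregation and statistical comparison of model arms.

Per-patient metrics are averaged across training seeds BEFORE any test;
arms are compared with two-sided Wilcoxon signed-rank tests on the paired
per-case differences (zeros discarded); volume agreement is an ordinary
least-squares fit of predicted on true lesion volume; boundary outliers are
cases whose HD95 exceeds a clinically motivated threshold (default 8 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

__all__ = [
    "aggregate_seeds",
    "paired_compare",
    "volume_agreement",
    "outlier_summary",
    "summarize_metrics",
    "PairedComparison",
]

_EXACT_N_MAX = 12  # exact signed-rank enumeration up to 2^12 sign vectors


@dataclass
class PairedComparison:
    metric: str
    n_pairs: int            # non-zero paired differences used
    p_value: float | None   # None when too few informative pairs
    median_difference: float
    insufficient: bool = False
    method: str = "exact"


def aggregate_seeds(runs: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-case arithmetic mean of each metric across seed repetitions.

    Every table must cover the identical case set; boolean flag columns are
    aggregated with ``any``.
    """
    if not runs:
        raise ValidationError("no metric tables given")
    base = set(runs[0]["case_id"])
    for i, df in enumerate(runs[1:], start=2):
        other = set(df["case_id"])
        if other != base:
            raise ValidationError(
                f"table {i} case set differs: only-in-first={sorted(base - other)} "
                f"only-in-table={sorted(other - base)}"
            )
    stacked = pd.concat(runs, ignore_index=True)
    bool_cols = [c for c in stacked.columns if stacked[c].dtype == bool]
    num_cols = [c for c in stacked.columns
                if c != "case_id" and c not in bool_cols
                and pd.api.types.is_numeric_dtype(stacked[c])]
    agg = {c: "mean" for c in num_cols} | {c: "any" for c in bool_cols}
    return stacked.groupby("case_id", as_index=False).agg(agg).sort_values(
        "case_id", ignore_index=True)


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign assignments.

    Uses average ranks for tied |differences| (so it remains exact under
    ties, unlike the normal approximation).  p = P(|W+ - E[W+]| >= |w - E[W+]|)
    under the null of symmetric signs.
    """
    n = diffs.size
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    signs = np.array(list(product((0.0, 1.0), repeat=n)))  # 2^n x n
    w_all = signs @ ranks
    center = ranks.sum() / 2.0
    p = np.mean(np.abs(w_all - center) >= np.abs(w_obs - center) - 1e-12)
    return float(min(1.0, p))


def paired_compare(a: pd.DataFrame, b: pd.DataFrame, metric: str,
                   min_pairs: int = 5) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank comparison of one metric across arms.

    Pairs are matched by case_id; zero differences are discarded (classic
    convention).  Fewer than ``min_pairs`` informative pairs yields an
    explicit "insufficient pairs" result rather than a p-value.  For
    n <= 12 the p-value is computed by exact enumeration; larger n defers
    to scipy's signed-rank test.
    """
    merged = a[["case_id", metric]].merge(
        b[["case_id", metric]], on="case_id", suffixes=("_a", "_b"))
    if len(merged) != len(a) or len(merged) != len(b):
        raise ValidationError("case sets differ between the two arms")
    diffs = (merged[f"{metric}_b"] - merged[f"{metric}_a"]).to_numpy(dtype=float)
    median_diff = float(np.median(diffs))
    nz = diffs[diffs != 0.0]
    if nz.size < min_pairs:
        return PairedComparison(metric, int(nz.size), None, median_diff,
                                insufficient=True, method="none")
    if nz.size <= _EXACT_N_MAX:
        return PairedComparison(metric, int(nz.size), _exact_signed_rank_p(nz),
                                median_diff, method="exact")
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided")
    return PairedComparison(metric, int(nz.size), float(res.pvalue),
                            median_diff, method="wilcoxon")


def volume_agreement(table: pd.DataFrame,
                     true_col: str = "true_volume_ml",
                     pred_col: str = "pred_volume_ml") -> tuple[float, float, float]:
    """OLS fit of predicted on true lesion volume: (slope, intercept, R^2)."""
    t = table[true_col].to_numpy(dtype=float)
    p = table[pred_col].to_numpy(dtype=float)
    ok = np.isfinite(t) & np.isfinite(p)
    t, p = t[ok], p[ok]
    if t.size < 3:
        raise ValidationError("need >= 3 cases with finite volumes")
    if np.ptp(t) == 0:
        raise ValidationError("zero variance in true volumes; slope undefined")
    res = stats.linregress(t, p)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def outlier_summary(table: pd.DataFrame, threshold_mm: float = 8.0,
                    other: pd.DataFrame | None = None) -> dict:
    """Cases whose HD95 exceeds the threshold; optionally, how many of those
    improved (strictly lower HD95) under a second arm."""
    if table.empty:
        raise ValidationError("empty metrics table")
    above = table[table["hd95_mm"] > threshold_mm]
    out = {
        "threshold_mm": threshold_mm,
        "count": int(len(above)),
        "case_ids": sorted(above["case_id"].tolist()),
    }
    if other is not None:
        merged = above[["case_id", "hd95_mm"]].merge(
            other[["case_id", "hd95_mm"]], on="case_id", suffixes=("_a", "_b"))
        out["improved_count"] = int((merged["hd95_mm_b"] < merged["hd95_mm_a"]).sum())
        out["improved_case_ids"] = sorted(
            merged.loc[merged["hd95_mm_b"] < merged["hd95_mm_a"], "case_id"].tolist())
    return out


def summarize_metrics(table: pd.DataFrame,
                      metrics=("dice", "hd95_mm", "sensitivity", "specificity")) -> pd.DataFrame:
    """Per-metric mean with a normal-approximation 95% CI (mean +/- 1.96 SE)."""
    rows = []
    for m in metrics:
        v = table[m].to_numpy(dtype=float)
        se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
        rows.append({"metric": m, "mean": v.mean(), "ci95": 1.96 * se, "n": v.size})
    return pd.DataFrame(rows)
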