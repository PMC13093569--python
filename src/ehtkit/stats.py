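"""Two-group comparisons and reporting conventions.

Groups (e.g. mutant vs rescue) are compared with unpaired two-tailed
Student's t tests (pooled variance by default, Welch behind a flag);
summaries are reported as mean ± SEM, and box summaries follow the
figure convention: box 25th–75th percentile, whiskers min–max,
horizontal line at the median.  No multiple-testing correction is
applied by default (per-feature tests are reported individually); a
Holm adjustment is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSample", "ComparisonResult", "compare_groups", "summarize",
           "holm_adjust"]


@dataclass
class GroupSample:
    """One feature's values for one group, one value per ROI or tissue."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).ravel()
        if self.values.size < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2 values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r}: non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        return float(sps.sem(self.values))

    def box_summary(self) -> dict:
        v = self.values
        return {"min": float(v.min()),
                "q25": float(np.percentile(v, 25)),
                "median": float(np.median(v)),
                "q75": float(np.percentile(v, 75)),
                "max": float(v.max())}


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    df: float
    p_value: float
    welch: bool
    box_a: dict = field(default_factory=dict)
    box_b: dict = field(default_factory=dict)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("group_a", "group_b", "mean_a", "sem_a", "mean_b", "sem_b",
                 "t_statistic", "df", "p_value", "welch", "degenerate",
                 "box_a", "box_b")}


def compare_groups(a: GroupSample, b: GroupSample,
                   welch: bool = False) -> ComparisonResult:
    """Unpaired two-tailed t test between two groups.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.  When both groups have zero variance and
    equal means the test is degenerate and p = 1 is reported by
    convention, flagged in the result.
    """
    va, vb = a.values, b.values
    degenerate = False
    if va.std() == 0 and vb.std() == 0 and va.mean() == vb.mean():
        t_stat, p, df = 0.0, 1.0, float(a.n + b.n - 2)
        degenerate = True
    else:
        res = sps.ttest_ind(va, vb, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return ComparisonResult(
        group_a=a.label, group_b=b.label,
        mean_a=a.mean, sem_a=a.sem, mean_b=b.mean, sem_b=b.sem,
        t_statistic=t_stat, df=df, p_value=p, welch=welch,
        box_a=a.box_summary(), box_b=b.box_summary(),
        degenerate=degenerate,
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def summarize(table: pd.DataFrame, group_col: str = "group",
              value_cols=None, welch: bool = False):
    """Per-feature group summaries and pairwise tests from a tidy table.

    Returns ``(summary_df, comparisons)``: the summary has one row per
    (feature, group) with n, mean, SEM and box statistics; for exactly
    two groups each feature is also tested with :func:`compare_groups`.
    Empty or all-NaN feature columns are dropped with a warning entry.
    """
    import warnings

    if group_col not in table.columns:
        raise ValueError(f"missing grouping column {group_col!r}")
    if value_cols is None:
        value_cols = [c for c in table.columns
                      if c != group_col and pd.api.types.is_numeric_dtype(table[c])]
    groups = list(dict.fromkeys(table[group_col]))
    rows, comparisons = [], {}
    for col in value_cols:
        col_ok = True
        samples = {}
        for g in groups:
            v = table.loc[table[group_col] == g, col].dropna().to_numpy(float)
            if v.size < 2:
                warnings.warn(f"feature {col!r}, group {g!r}: fewer than 2 "
                              "values; feature skipped", stacklevel=2)
                col_ok = False
                break
            samples[g] = GroupSample(label=str(g), values=v)
        if not col_ok:
            continue
        for g, s in samples.items():
            rows.append({"feature": col, "group": g, "n": s.n,
                         "mean": s.mean, "sem": s.sem, **s.box_summary()})
        if len(groups) == 2:
            comparisons[col] = compare_groups(*samples.values(), welch=welch)
    return pd.DataFrame(rows), comparisons


def format_report(summary: pd.DataFrame, comparisons: dict) -> str:
    """Human-readable mean ± SEM report with exact p values."""
    lines = []
    for feature, comp in comparisons.items():
        lines.append(
            f"{feature}: {comp.group_a} {comp.mean_a:.4g} ± {comp.sem_a:.2g} "
            f"vs {comp.group_b} {comp.mean_b:.4g} ± {comp.sem_b:.2g}  "
            f"(t = {comp.t_statistic:.3f}, df = {comp.df:.3g}, "
            f"p = {comp.p_value:.3g}{', degenerate' if comp.degenerate else ''})")
    if not lines:
        for _, r in summary.iterrows():
            lines.append(f"{r['feature']} [{r['group']}]: "
                         f"{r['mean']:.4g} ± {r['sem']:.2g} (n = {r['n']})")
    return "\n".join(lines)
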