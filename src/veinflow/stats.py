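"""Nonparametric cohort statistics: rank-sum group comparisons, rank
correlations of segment trends, and the high-velocity contingency test.

Conventions fixed here and used everywhere:

* Mann-Whitney U is two-sided; the exact null distribution is used when
  both groups have n <= 10 and there are no ties, otherwise the normal
  approximation with tie correction.
* Quantiles use linear interpolation (numpy default).
* Trend correlations pool all subjects' per-segment values (segment index
  as x); both Spearman and Pearson coefficients are reported, and |R| > 0.5
  is labelled a strong relationship.
* Significance threshold alpha = 0.05; no multiple-testing correction is
  applied (descriptive parity with small-cohort practice - a caveat, not
  a recommendation).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .summary import VeinRecord, group_segment_table

__all__ = [
    "StatResult",
    "GroupComparison",
    "mann_whitney",
    "spearman_trend",
    "pearson_trend",
    "high_velocity_contingency",
    "compare_groups",
    "pooled_segment_values",
    "COMPARABLE_VARIABLES",
]

STRONG_R = 0.50


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    effect_direction: int  # +1: first group/positive trend, -1: opposite, 0: none
    n_per_group: tuple[int, ...]
    estimate: float | None = None  # correlation R or median difference
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.degenerate and not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < 0.05

    @property
    def strong(self) -> bool:
        """Strength label for correlations: |R| above 0.50."""
        return self.estimate is not None and abs(self.estimate) > STRONG_R


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], method: str = "auto"
) -> StatResult:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    ``method``: "auto" (exact when both n <= 10 and no ties), "exact" or
    "asymptotic" (normal approximation with tie correction).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if method == "auto":
        method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) else "asymptotic"
    if method == "exact" and has_ties:
        method = "asymptotic"  # exact distribution is invalid under ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    direction = int(np.sign(u1 - a.size * b.size / 2.0))
    return StatResult(
        test_name=f"mann-whitney-{method}",
        statistic=u1,
        p_value=float(min(res.pvalue, 1.0)),
        effect_direction=direction,
        n_per_group=(a.size, b.size),
        estimate=float(np.median(a) - np.median(b)),
    )


def _trend(x: Sequence[float], y: Sequence[float], kind: str) -> StatResult:
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(yv == yv[0]) or np.all(xv == xv[0]):
        return StatResult(
            test_name=f"{kind}-trend",
            statistic=0.0,
            p_value=1.0,
            effect_direction=0,
            n_per_group=(xv.size,),
            estimate=None,
            degenerate=True,
        )
    if kind == "spearman":
        rho, p = sps.spearmanr(xv, yv)
    else:
        rho, p = sps.pearsonr(xv, yv)
    return StatResult(
        test_name=f"{kind}-trend",
        statistic=float(rho),
        p_value=float(p),
        effect_direction=int(np.sign(rho)),
        n_per_group=(xv.size,),
        estimate=float(rho),
    )


def spearman_trend(segment_indices: Sequence[float], values: Sequence[float]) -> StatResult:
    """Tie-corrected Spearman rank correlation of value against segment index.

    Constant input yields a flagged degenerate result rather than NaN.
    """
    return _trend(segment_indices, values, "spearman")


def pearson_trend(segment_indices: Sequence[float], values: Sequence[float]) -> StatResult:
    """Pearson linear correlation companion to :func:`spearman_trend`."""
    return _trend(segment_indices, values, "pearson")


def high_velocity_contingency(
    flagged_a: int,
    total_a: int,
    flagged_b: int,
    total_b: int,
    method: str = "chi2",
) -> StatResult:
    """Test association of the high-velocity flag with group membership on
    the 2x2 segment table.

    ``method='chi2'`` is Pearson's chi-squared without continuity
    correction; ``'fisher'`` the exact test.  Percentages ``flagged/total``
    are reported to one decimal in ``extra``.
    """
    for flagged, total in ((flagged_a, total_a), (flagged_b, total_b)):
        if total <= 0:
            raise ValueError("group totals must be positive")
        if not 0 <= flagged <= total:
            raise ValueError("flagged count must lie in [0, total]")
    table = np.array(
        [[flagged_a, total_a - flagged_a], [flagged_b, total_b - flagged_b]]
    )
    pct_a = round(100.0 * flagged_a / total_a, 1)
    pct_b = round(100.0 * flagged_b / total_b, 1)
    if method == "chi2":
        if np.any(table.sum(axis=0) == 0):
            stat, p = 0.0, 1.0
        else:
            res = sps.chi2_contingency(table, correction=False)
            stat, p = float(res.statistic), float(res.pvalue)
        name = "chi-squared"
    elif method == "fisher":
        stat, p = sps.fisher_exact(table, alternative="two-sided")
        stat, p = float(stat), float(p)
        name = "fisher-exact"
    else:
        raise ValueError(f"unknown method {method!r}")
    direction = int(np.sign(pct_a - pct_b))
    return StatResult(
        test_name=name,
        statistic=stat,
        p_value=p,
        effect_direction=direction,
        n_per_group=(total_a, total_b),
        estimate=pct_a - pct_b,
        extra={"percent_a": pct_a, "percent_b": pct_b, "table": table.tolist()},
    )


# ---------------------------------------------------------------------------
# record-level comparisons

COMPARABLE_VARIABLES = (
    "inlet_area",
    "exit_area",
    "area_ratio",
    "absolute_length",
    "actual_length",
    "tortuosity_index",
    "wss_avg",
    "wss_max",
    "pressure_avg",
    "pressure_max",
    "n_high_velocity",
    "group_pressure_A",
    "group_pressure_B",
    "group_pressure_C",
    "group_wss_A",
    "group_wss_B",
    "group_wss_C",
    "group_velocity_A",
    "group_velocity_B",
    "group_velocity_C",
)


@dataclass(frozen=True)
class GroupComparison:
    """Median [IQR] per group plus the rank-sum test for one variable."""

    variable: str
    median_a: float
    q1_a: float
    q3_a: float
    median_b: float
    q1_b: float
    q3_b: float
    test: StatResult

    def format_row(self) -> str:
        return (
            f"{self.variable}\t"
            f"{self.median_a:.2f} [{self.q1_a:.2f}, {self.q3_a:.2f}]\t"
            f"{self.median_b:.2f} [{self.q1_b:.2f}, {self.q3_b:.2f}]\t"
            f"{self.test.p_value:.4g}"
        )


def _extract(record: VeinRecord, variable: str) -> float:
    if variable.startswith("group_"):
        _, quantity, group = variable.split("_")
        from .summary import group_value

        return group_value(record, group, quantity)
    if not hasattr(record, variable):
        raise ValueError(f"unknown variable {variable!r}")
    return float(getattr(record, variable))


def compare_groups(
    records: Sequence[VeinRecord], variable: str, method: str = "auto"
) -> GroupComparison:
    """Ruptured-vs-unruptured comparison of one subject-level variable."""
    a = np.array([_extract(r, variable) for r in records if r.ruptured])
    b = np.array([_extract(r, variable) for r in records if not r.ruptured])
    if a.size == 0 or b.size == 0:
        raise ValueError("both rupture groups must be nonempty")
    q1a, meda, q3a = np.quantile(a, [0.25, 0.5, 0.75])
    q1b, medb, q3b = np.quantile(b, [0.25, 0.5, 0.75])
    return GroupComparison(
        variable=variable,
        median_a=float(meda),
        q1_a=float(q1a),
        q3_a=float(q3a),
        median_b=float(medb),
        q1_b=float(q1b),
        q3_b=float(q3b),
        test=mann_whitney(a, b, method=method),
    )


def pooled_segment_values(
    records: Sequence[VeinRecord], quantity: str, ruptured: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-segment values across subjects of one rupture group.

    Returns ``(segment_indices, values)`` with one point per
    subject-segment (e.g. 6 subjects x 15 segments = 90 points).
    """
    attr = {"pressure": "pressure_avg", "wss": "wss_avg", "velocity": "velocity_avg"}[
        quantity
    ]
    xs: list[int] = []
    ys: list[float] = []
    for r in records:
        if r.ruptured != ruptured:
            continue
        for s in r.segments:
            xs.append(s.segment_index)
            ys.append(getattr(s, attr))
    if not xs:
        raise ValueError("no records in the requested rupture group")
    return np.array(xs, dtype=float), np.array(ys, dtype=float)
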