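"""Group comparisons for per-cell metrics.

Pairwise two-sample t-tests (Student or Welch) with Bonferroni adjustment
over the declared number of comparisons, plus per-group box-plot summary
statistics (n, mean, median, interquartile range, total range).  One-way
ANOVA is exposed as a conventional-test wrapper for multi-group screening;
the bespoke science lives upstream of these routines.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as _stats


class GroupTestError(ValueError):
    """Group unusable for testing (n < 2)."""


@dataclass(frozen=True)
class GroupSummary:
    """Box-plot statistics of one group."""

    label: str
    n: int
    mean: float
    median: float
    iqr: tuple[float, float]
    range: tuple[float, float]


@dataclass(frozen=True)
class PairwiseTest:
    """One pairwise t-test with its multiplicity-adjusted p-value."""

    group_a: str
    group_b: str
    t_statistic: float
    p_raw: float
    p_adjusted: float
    method: str


@dataclass(frozen=True)
class GroupComparison:
    """All pairwise comparisons of one metric across groups."""

    metric: str
    summaries: list[GroupSummary]
    tests: list[PairwiseTest]
    adjustment: str

    def summary(self) -> str:
        lines = [f"Metric: {self.metric}", "-" * 60]
        for s in self.summaries:
            lines.append(
                f"{s.label:>12s}  n={s.n:<3d} mean={s.mean:8.3f} "
                f"median={s.median:8.3f} IQR=[{s.iqr[0]:.3f}, {s.iqr[1]:.3f}]"
            )
        for t in self.tests:
            lines.append(
                f"{t.group_a} vs {t.group_b}: t={t.t_statistic:7.3f} "
                f"p={t.p_raw:.3g} adj={t.p_adjusted:.3g} ({t.method})"
            )
        return "\n".join(lines)


def _summarize(label: str, values: np.ndarray) -> GroupSummary:
    q1, q3 = np.percentile(values, [25, 75])
    return GroupSummary(
        label=label,
        n=len(values),
        mean=float(values.mean()),
        median=float(np.median(values)),
        iqr=(float(q1), float(q3)),
        range=(float(values.min()), float(values.max())),
    )


def bonferroni(p_values, comparisons: int | None = None) -> np.ndarray:
    """Bonferroni adjustment, clipped to 1; preserves the raw-p ordering."""
    p = np.asarray(p_values, dtype=float)
    m = comparisons if comparisons is not None else len(p)
    return np.minimum(p * m, 1.0)


def holm(p_values) -> np.ndarray:
    """Holm step-down adjustment, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def compare_groups(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    metric: str = "",
    adjustment: str = "bonferroni",
    comparisons: int | None = None,
    equal_var: bool = False,
) -> GroupComparison:
    """Pairwise t-tests across groups with multiplicity adjustment.

    ``comparisons`` declares the total number of comparisons the adjustment
    should account for (default: the number of pairs tested here).  Welch's
    unequal-variance test is the default; pass ``equal_var=True`` for the
    classical Student test.
    """
    if len(values_by_group) < 2:
        raise GroupTestError("need at least 2 groups to compare")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for label, vals in groups.items():
        if len(vals) < 2:
            raise GroupTestError(f"group {label!r} has n={len(vals)} (< 2)")
    summaries = [_summarize(k, v) for k, v in groups.items()]
    pairs = list(combinations(groups, 2))
    raws, tstats = [], []
    for a, b in pairs:
        t, p = _stats.ttest_ind(groups[a], groups[b], equal_var=equal_var)
        tstats.append(float(t))
        raws.append(float(p))
    if adjustment == "bonferroni":
        adj = bonferroni(raws, comparisons if comparisons is not None else len(pairs))
    elif adjustment == "holm":
        adj = holm(raws)
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    name = ("Student t" if equal_var else "Welch t") + f" + {adjustment}"
    tests = [
        PairwiseTest(a, b, t, p, float(q), name)
        for (a, b), t, p, q in zip(pairs, tstats, raws, adj)
    ]
    return GroupComparison(metric=metric, summaries=summaries, tests=tests,
                           adjustment=adjustment)


def one_way_anova(values_by_group: dict) -> tuple[float, float]:
    """Conventional one-way ANOVA F-test across all groups (delegated)."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise GroupTestError("need at least 2 groups")
    f, p = _stats.f_oneway(*groups)
    return float(f), float(p)
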