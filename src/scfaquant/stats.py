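"""Group comparisons for concentration data.

Two-group comparisons use the pooled-variance Student's t-test (Welch
available via a flag); multi-group comparisons use one-way ANOVA followed
by Tukey's HSD for all pairwise contrasts. Dixon's Q-test (r10 statistic)
screens small replicate sets for a single gross outlier before testing.
P-values map to the usual significance stars: * <0.05, ** <0.01,
*** <0.001, **** <0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

STAR_THRESHOLDS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]

# Dixon r10 critical values, n = 3..10
_DIXON_CRITICAL = {
    0.90: [0.941, 0.765, 0.642, 0.560, 0.507, 0.468, 0.437, 0.412],
    0.95: [0.970, 0.829, 0.710, 0.625, 0.568, 0.526, 0.493, 0.466],
    0.99: [0.994, 0.926, 0.821, 0.740, 0.680, 0.634, 0.598, 0.568],
}


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    stars: str


@dataclass(frozen=True)
class GroupComparisonResult:
    test: str
    statistic: float
    p_value: float
    stars: str
    pairwise: list[PairwiseResult] = field(default_factory=list)


def students_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> GroupComparisonResult:
    """Two-sided two-sample t-test (pooled variance unless ``welch``).

    Degenerate case: zero variance in both groups gives p = 1 for equal
    means and p = 0 for unequal means.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return GroupComparisonResult("t-test", 0.0, 1.0, "ns")
        return GroupComparisonResult(
            "t-test", np.inf if a[0] > b[0] else -np.inf, 0.0, "****"
        )
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparisonResult("t-test", float(t), float(p), significance_stars(p))


def one_way_anova_tukey(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> GroupComparisonResult:
    """One-way ANOVA omnibus test plus Tukey HSD pairwise contrasts."""
    if len(groups) < 3:
        raise ValueError("ANOVA + Tukey requires >= 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    if np.ptp(np.concatenate(arrays)) == 0:
        pairwise = [
            PairwiseResult(labels[i], labels[j], 0.0, 1.0, "ns")
            for i in range(len(arrays))
            for j in range(i + 1, len(arrays))
        ]
        return GroupComparisonResult("anova", 0.0, 1.0, "ns", pairwise)
    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            pij = float(hsd.pvalue[i, j])
            pairwise.append(
                PairwiseResult(
                    labels[i],
                    labels[j],
                    float(hsd.statistic[i, j]),
                    pij,
                    significance_stars(pij),
                )
            )
    return GroupComparisonResult(
        "anova", float(f), float(p), significance_stars(float(p)), pairwise
    )


def dixon_q_test(
    values: Sequence[float], confidence: float = 0.95
) -> tuple[list[float], list[int]]:
    """Single-pass Dixon Q screen; rejects at most one extreme value.

    Q = (gap between the suspect extreme and its nearest neighbour) /
    (range). The larger of the low-end and high-end Q values is compared
    with the tabulated critical value for 3 ≤ n ≤ 10.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if not 3 <= n <= 10:
        raise ValueError(f"Dixon Q is tabulated for n in 3..10, got {n}")
    try:
        critical = _DIXON_CRITICAL[confidence][n - 3]
    except KeyError:
        raise ValueError(
            f"confidence must be one of {sorted(_DIXON_CRITICAL)}, got {confidence}"
        ) from None
    order = np.argsort(x, kind="stable")
    xs = x[order]
    rng = xs[-1] - xs[0]
    if rng == 0:
        return list(values), []
    q_low = (xs[1] - xs[0]) / rng
    q_high = (xs[-1] - xs[-2]) / rng
    if q_high >= q_low:
        q, suspect = q_high, int(order[-1])
    else:
        q, suspect = q_low, int(order[0])
    if q > critical:
        kept = [v for i, v in enumerate(values) if i != suspect]
        return kept, [suspect]
    return list(values), []
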