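"""Two-sample and multi-group comparisons used throughout the study.

Thin, explicit wrappers around scipy.stats with the conventions fixed:
two-sided p-values, pooled-variance Student's t by default (Welch by flag),
Wilcoxon rank-sum (Mann–Whitney) exact for small tie-free samples and
normal-approximated with midranks and tie correction otherwise, and one-way
ANOVA. Degenerate inputs (zero variance) return the limiting results instead
of NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    group_labels: tuple[str, ...]
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def describe(sample) -> tuple[int, float, float]:
    """(n, mean, sample SD with n−1 denominator); single value → sd 0."""
    x = np.asarray(sample, dtype=float)
    if x.size < 1:
        raise ValueError("empty sample")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return int(x.size), float(x.mean()), sd


def students_t(group_a, group_b, labels=("a", "b"),
               welch: bool = False) -> ComparisonResult:
    """Two-sample Student's t (pooled variance; Welch optional), two-sided."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2 for a t-test")
    flags = ()
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return ComparisonResult("welch_t" if welch else "students_t",
                                    tuple(labels), 0.0, 1.0,
                                    (a.size, b.size), ("zero_variance",))
        flags = ("zero_variance",)
        stat, p = np.inf if a.mean() > b.mean() else -np.inf, 0.0
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult("welch_t" if welch else "students_t",
                            tuple(labels), float(stat), float(p),
                            (a.size, b.size), flags)


def wilcoxon_rank_sum(group_a, group_b, labels=("a", "b"),
                      exact_max_n: int = 20) -> ComparisonResult:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney U), two-sided.

    Exact null distribution when the pooled sample is small (≤
    ``exact_max_n``) and tie-free; otherwise the normal approximation with
    midranks, tie correction and continuity correction. The reported
    statistic is the U of the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs n >= 1")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return ComparisonResult("wilcoxon_rank_sum", tuple(labels),
                                a.size * b.size / 2.0, 1.0,
                                (a.size, b.size), ("all_identical",))
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (a.size + b.size) <= exact_max_n and not has_ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if use_exact else "asymptotic")
    flags = ("exact",) if use_exact else ("normal_approximation",)
    return ComparisonResult("wilcoxon_rank_sum", tuple(labels),
                            float(res.statistic), float(min(res.pvalue, 1.0)),
                            (a.size, b.size), flags)


def one_way_anova(groups, labels=None) -> ComparisonResult:
    """One-way ANOVA: F = MS_between / MS_within, p from the F distribution."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    labels = tuple(labels) if labels else tuple(str(i) for i in range(len(arrays)))
    ns = tuple(a.size for a in arrays)
    if all(a.std(ddof=1) == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        if np.ptp(means) == 0:
            return ComparisonResult("one_way_anova", labels, 0.0, 1.0, ns,
                                    ("zero_variance",))
        return ComparisonResult("one_way_anova", labels, np.inf, 0.0, ns,
                                ("zero_within_variance",))
    stat, p = stats.f_oneway(*arrays)
    return ComparisonResult("one_way_anova", labels, float(stat), float(p), ns)


def simulate_type_i_error(test: str, n_per_group: int, n_sims: int = 10_000,
                          alpha: float = 0.05, seed=0) -> float:
    """Null rejection rate of a test over simulated same-distribution groups.

    Vectorized over simulations; groups are standard normal. ``test`` is one
    of "t", "wilcoxon", "anova".
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = rng.standard_normal((n_sims, n_per_group))
    b = rng.standard_normal((n_sims, n_per_group))
    if test == "t":
        p = stats.ttest_ind(a, b, axis=1).pvalue
    elif test == "wilcoxon":
        p = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided",
                               method="asymptotic").pvalue
    elif test == "anova":
        p = stats.f_oneway(a, b, axis=1).pvalue
    else:
        raise ValueError(f"unknown test '{test}'")
    return float(np.mean(p < alpha))
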