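"""Group-comparison statistics: Welch t, Wilcoxon rank sum, paired t.

All tests are two-sided.  The Wilcoxon rank-sum test is computed as the
equivalent Mann-Whitney U with an exact small-sample p-value when there are
no ties (falling back to the normal approximation otherwise).  A
summary-statistic Welch test is provided for published mean/SEM/n triples
where raw values are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import AnalysisError, ValidationError

__all__ = ["GroupComparison", "compare_groups", "welch_t_from_summary"]

_METHODS = ("welch_t", "wilcoxon_rank_sum", "paired_t")


@dataclass(frozen=True)
class GroupComparison:
    labels: tuple[str, str]
    method: str
    statistic: float
    p_value: float
    n: tuple[int, int]
    values: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p_value must lie in [0, 1]")


def compare_groups(
    a,
    b,
    method: str = "welch_t",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided comparison of two groups of values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method not in _METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {_METHODS}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("group values must be finite")
    if method == "paired_t":
        if a.size != b.size:
            raise ValidationError("paired_t requires equal group sizes")
        if a.size < 2:
            raise ValidationError("paired_t requires n >= 2 pairs")
        d = a - b
        if np.all(d == d[0]) and d.std() == 0 and d[0] == 0:
            stat, p = 0.0, 1.0
        else:
            res = sps.ttest_rel(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        if a.size < 2 or b.size < 2:
            raise ValidationError("unpaired tests require n >= 2 per group")
        if method == "welch_t":
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                if np.isclose(a.mean(), b.mean()):
                    stat, p = 0.0, 1.0
                else:
                    raise AnalysisError(
                        "zero variance in both groups: Welch statistic undefined"
                    )
            else:
                res = sps.ttest_ind(a, b, equal_var=False)
                stat, p = float(res.statistic), float(res.pvalue)
        else:  # wilcoxon_rank_sum == Mann-Whitney U
            ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
            use_exact = not ties and (a.size + b.size) <= 25
            res = sps.mannwhitneyu(
                a, b, alternative="two-sided",
                method="exact" if use_exact else "asymptotic",
            )
            # report the rank-sum W of group a (U + n_a(n_a+1)/2)
            stat = float(res.statistic + a.size * (a.size + 1) / 2)
            p = float(res.pvalue)
    return GroupComparison(labels, method, stat, min(p, 1.0),
                           (int(a.size), int(b.size)), (a, b))


def welch_t_from_summary(
    mean_a: float, sem_a: float, n_a: int,
    mean_b: float, sem_b: float, n_b: int,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Welch t-test from published mean +/- SEM summaries (sd = sem*sqrt(n))."""
    if n_a < 2 or n_b < 2:
        raise ValidationError("summary Welch test requires n >= 2 per group")
    if sem_a == 0 and sem_b == 0:
        raise AnalysisError("zero variance in both groups: Welch statistic undefined")
    res = sps.ttest_ind_from_stats(
        mean_a, sem_a * np.sqrt(n_a), n_a,
        mean_b, sem_b * np.sqrt(n_b), n_b,
        equal_var=False,
    )
    return GroupComparison(labels, "welch_t", float(res.statistic),
                           float(res.pvalue), (int(n_a), int(n_b)))
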