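"""Survival and nonparametric statistics.

Kaplan-Meier product-limit estimation with Greenwood variance, the
Mantel-Cox log-rank test (hypergeometric observed-vs-expected with tied
deaths handled by the standard variance with multiplicities), pairwise
log-rank with Bonferroni correction over all unordered group pairs, and
the Wilcoxon rank-sum test (exact by enumeration for small tie-free
samples, else normal approximation with tie and continuity corrections).

Survival tables are DataFrames with columns ``subject_id, group,
time_days, event`` (event 1 = died, 0 = censored).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    InvalidArgumentError,
    InvalidInputError,
    LookupError_,
    UndefinedStatisticError,
)

__all__ = [
    "KaplanMeierEstimate",
    "TestResult",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank_bonferroni",
    "validate_survival_table",
    "wilcoxon_rank_sum",
]

REQUIRED_COLUMNS = ("subject_id", "group", "time_days", "event")


def validate_survival_table(tab: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(tab.columns)
    if missing:
        raise InvalidInputError(f"survival table missing columns: {sorted(missing)}")
    if len(tab) == 0:
        raise InvalidInputError("survival table is empty")
    if (tab["time_days"] <= 0).any():
        raise InvalidInputError("event/censoring times must be > 0")
    if not tab["event"].isin([0, 1]).all():
        raise InvalidInputError("event flags must be 0 or 1")
    return tab


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest case despite the name

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidInputError("p_value must lie in [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise InvalidInputError("p_adjusted must be >= p_value")


@dataclass
class KaplanMeierEstimate:
    """Right-continuous product-limit step function with Greenwood variance."""

    event_times: np.ndarray  # distinct death times, sorted
    survival: np.ndarray  # S(t) just after each event time
    variance: np.ndarray  # Greenwood variance of S at each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    group: str = ""

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate S(t); S(0) = 1, steps occur at event times."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if out.ndim == 0 else out


def km_estimate(tab: pd.DataFrame, group: str) -> KaplanMeierEstimate:
    """Kaplan-Meier estimator for one group of a survival table."""
    validate_survival_table(tab)
    sub = tab[tab["group"] == group]
    if len(sub) == 0:
        raise LookupError_(
            f"unknown group {group!r}; available: {sorted(tab['group'].unique())}"
        )
    times = sub["time_days"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=int)

    death_times = np.unique(times[events == 1])
    s = 1.0
    greenwood_sum = 0.0
    surv, var, at_risk, n_ev = [], [], [], []
    for t in death_times:
        n = int(np.sum(times >= t))  # at risk just before t
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n
        if n > d:
            greenwood_sum += d / (n * (n - d))
            var.append(s**2 * greenwood_sum)
        else:
            var.append(0.0)  # S = 0: variance degenerate
        surv.append(s)
        at_risk.append(n)
        n_ev.append(d)
    return KaplanMeierEstimate(
        event_times=death_times,
        survival=np.array(surv),
        variance=np.array(var),
        n_at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_ev, dtype=int),
        group=group,
    )


def logrank_test(tab: pd.DataFrame, group_a: str, group_b: str) -> TestResult:
    """Two-group Mantel-Cox log-rank test.

    At each distinct death time the observed deaths in group A are
    compared with their hypergeometric expectation given the pooled risk
    set; the statistic (sum(O-E))^2 / sum(Var) is referred to chi-square
    with 1 df.
    """
    validate_survival_table(tab)
    sub = tab[tab["group"].isin([group_a, group_b])]
    n_a_total = int((sub["group"] == group_a).sum())
    n_b_total = int((sub["group"] == group_b).sum())
    if n_a_total == 0 or n_b_total == 0:
        raise InvalidInputError("both groups need at least one subject")

    times = sub["time_days"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=int)
    in_a = (sub["group"] == group_a).to_numpy()

    death_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var_sum = 0.0
    for t in death_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var_sum += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var_sum == 0:
        stat, p = 0.0, 1.0
    else:
        stat = o_minus_e**2 / var_sum
        p = float(sps.chi2.sf(stat, df=1))
    return TestResult(
        statistic=float(stat),
        p_value=p,
        method="logrank",
        n_per_group=(n_a_total, n_b_total),
    )


def pairwise_logrank_bonferroni(tab: pd.DataFrame) -> pd.DataFrame:
    """Log-rank tests for all unordered group pairs, Bonferroni-adjusted.

    The Bonferroni family is all C(k, 2) pairs in the table;
    p_adjusted = min(1, p * n_pairs).  Returns one row per pair.
    """
    validate_survival_table(tab)
    groups = sorted(tab["group"].unique())
    if len(groups) < 2:
        raise InvalidInputError("need >= 2 groups for pairwise comparison")
    pairs = list(combinations(groups, 2))
    rows = []
    for a, b in pairs:
        res = logrank_test(tab, a, b)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "p_adjusted": min(1.0, res.p_value * len(pairs)),
                "n_a": res.n_per_group[0],
                "n_b": res.n_per_group[1],
                "n_pairs": len(pairs),
            }
        )
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(
    x: list | np.ndarray, y: list | np.ndarray, exact_max_n: int = 10
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic reported is the rank sum of ``x`` with midranks for
    ties.  The p-value is exact (full enumeration of rank assignments)
    when both samples have at most ``exact_max_n`` observations and there
    are no ties across the pooled sample; otherwise the normal
    approximation with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    w = float(ranks[: x.size].sum())
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size <= exact_max_n and y.size <= exact_max_n and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
    return TestResult(
        statistic=w,
        p_value=min(p, 1.0),
        method=f"wilcoxon-rank-sum ({method})",
        n_per_group=(int(x.size), int(y.size)),
    )
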