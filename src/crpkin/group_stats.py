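"""Cohort comparison statistics.

Per-day group comparisons of the CRP course (Welch t-tests across
calendar days, corrected by the Benjamini-Krieger-Yekutieli two-stage
step-up FDR procedure), standard two-group tests for cohort tables
(Mann-Whitney, Fisher's exact, chi-square), and the a-priori sample-size
computation for a point-biserial correlation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

__all__ = [
    "DailyComparison",
    "PowerSpec",
    "GroupStatsError",
    "per_day_comparison",
    "bky_fdr",
    "bky_rejections",
    "bh_rejections",
    "holm_sidak",
    "two_group_tests",
    "mann_whitney",
    "fisher_exact_2x2",
    "chi_square",
    "sample_size_point_biserial",
]


class GroupStatsError(ValueError):
    """Raised on degenerate statistical inputs."""


@dataclass
class DailyComparison:
    """One calendar day's between-group CRP comparison."""

    day: int
    n0: int
    n1: int
    mean0: float
    mean1: float
    p_value: float
    q_value: float
    significant: bool


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of the point-biserial sample-size computation."""

    rho: float
    alpha: float = 0.05
    power: float = 0.95
    tails: Literal["one", "two"] = "one"

    def __post_init__(self) -> None:
        for nm, v in (("rho", self.rho), ("alpha", self.alpha), ("power", self.power)):
            if not 0 < v < 1:
                raise GroupStatsError(f"{nm} must be in (0, 1), got {v}")
        if self.tails not in ("one", "two"):
            raise GroupStatsError(f"tails must be 'one' or 'two', got {self.tails}")


# ---------------------------------------------------------------------------
# multiplicity corrections


def bh_rejections(pvalues: Sequence[float], alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level alpha."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= alpha * (np.arange(1, m + 1) / m)
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


def bky_rejections(pvalues: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Two-stage step-up rejection set at level alpha.

    Stage 1 runs Benjamini-Hochberg at alpha' = alpha/(1+alpha); the
    rejection count r1 estimates the number of true nulls m0 = m - r1.
    If r1 = 0 nothing is rejected; if r1 = m everything is.  Stage 2
    reruns Benjamini-Hochberg at alpha' * m / m0.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    alpha_prime = alpha / (1.0 + alpha)
    stage1 = bh_rejections(p, alpha_prime)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    return bh_rejections(p, alpha_prime * m / m0)


def bky_fdr(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Krieger-Yekutieli two-stage adaptive FDR.

    Returns ``(q_values, rejected)`` where ``rejected`` is the two-stage
    rejection mask at ``alpha`` and each q-value is the smallest level at
    which that p-value would be rejected (found by bisection on the
    rejection function, which is monotone in the level).

    Empty input returns empty arrays.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise GroupStatsError("p-values must lie in [0, 1]")
    rejected = bky_rejections(p, alpha)

    q = np.ones(p.size)
    for i in np.argsort(p, kind="stable"):
        lo, hi = 0.0, 1.0
        if not bky_rejections(p, 1.0 - 1e-12)[i]:
            q[i] = 1.0
            continue
        for _ in range(50):
            mid = (lo + hi) / 2.0
            if bky_rejections(p, mid)[i]:
                hi = mid
            else:
                lo = mid
        q[i] = hi
    # enforce monotonicity of q in p (bisection noise is ~1e-15)
    order = np.argsort(p, kind="stable")
    q[order] = np.maximum.accumulate(q[order])
    return q, rejected


def holm_sidak(pvalues: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm-Sidak step-down rejection mask (family-wise error control)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    mask = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= 1.0 - (1.0 - alpha) ** (1.0 / (m - rank)):
            mask[idx] = True
        else:
            break
    return mask


# ---------------------------------------------------------------------------
# per-day CRP comparison


_GROUPERS = {
    "infection": lambda r: int(r.infection),
    "indication": lambda r: int(r.indication_trauma),
    # anterolateral (1) vs posterior (2); other approaches are dropped
    "approach": lambda r: {1: 0, 2: 1}.get(r.approach),
}


def per_day_comparison(
    cohort: CohortTable,
    grouping: Literal["infection", "approach", "indication"] = "infection",
    alpha: float = 0.05,
    min_per_group: int = 2,
) -> list[DailyComparison]:
    """Welch t-test of CRP between groups on every shared calendar day.

    Days with fewer than ``min_per_group`` observations in either group
    are excluded from the family.  q-values come from :func:`bky_fdr`
    over the remaining days; a day is significant at q <= alpha.
    """
    if grouping not in _GROUPERS:
        raise GroupStatsError(f"unknown grouping '{grouping}'")
    assign = _GROUPERS[grouping]
    group_of = {r.patient_id: assign(r) for r in cohort.records}

    rows: list[tuple[int, np.ndarray, np.ndarray]] = []
    by_day: dict[int, tuple[list[float], list[float]]] = {}
    for pid, series in cohort.series.items():
        g = group_of.get(pid)
        if g is None:
            continue
        for m in series:
            by_day.setdefault(m.day, ([], []))[g].append(m.value)
    for day in sorted(by_day):
        g0, g1 = by_day[day]
        if len(g0) >= min_per_group and len(g1) >= min_per_group:
            rows.append((day, np.array(g0), np.array(g1)))
    if not rows:
        raise GroupStatsError("no day has enough observations in both groups")

    pvals = np.array(
        [stats.ttest_ind(g1, g0, equal_var=False).pvalue for _, g0, g1 in rows]
    )
    qvals, rejected = bky_fdr(pvals, alpha=alpha)
    return [
        DailyComparison(
            day=day,
            n0=len(g0),
            n1=len(g1),
            mean0=float(np.mean(g0)),
            mean1=float(np.mean(g1)),
            p_value=float(p),
            q_value=float(q),
            significant=bool(rej),
        )
        for (day, g0, g1), p, q, rej in zip(rows, pvals, qvals, rejected)
    ]


def comparison_frame(comparisons: list[DailyComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "day": c.day,
                "n0": c.n0,
                "n1": c.n1,
                "mean0": c.mean0,
                "mean1": c.mean1,
                "p": c.p_value,
                "q": c.q_value,
                "significant": int(c.significant),
            }
            for c in comparisons
        ]
    )


# ---------------------------------------------------------------------------
# two-group tests


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 400
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: (U statistic, p).

    Exact by enumeration when n1*n2 <= exact_limit and the pooled data
    are tie-free; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise GroupStatsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= exact_limit and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Fisher's exact two-sided p for a 2x2 count table.

    Two-sided by the point-probability method: sum of all hypergeometric
    outcomes no more probable than the observed table.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise GroupStatsError("need a non-negative 2x2 table")
    if t.sum() == 0:
        raise GroupStatsError("degenerate table: all counts zero")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square test of independence: (statistic, p)."""
    t = np.asarray(table, dtype=float)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise GroupStatsError("degenerate table: empty row or column")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def two_group_tests(
    cohort: CohortTable,
    variable: str,
    grouping: Literal["infection", "approach", "indication"] = "infection",
) -> dict:
    """Standard two-group test for one covariate of the cohort table.

    Continuous covariates get a Mann-Whitney test; dichotomous ones get
    Fisher's exact test on the 2x2 counts.  Returns a small report dict
    with the test name, statistic/p, and per-group summaries.
    """
    assign = _GROUPERS[grouping]
    df = cohort.patients_frame()
    df["_group"] = [assign(r) for r in cohort.records]
    df = df[df["_group"].notna()]
    if variable not in df.columns:
        raise GroupStatsError(f"unknown covariate '{variable}'")
    g0 = df.loc[df["_group"] == 0, variable]
    g1 = df.loc[df["_group"] == 1, variable]
    values = pd.concat([g0, g1])
    if set(pd.unique(values)) <= {0, 1}:
        table = [
            [int((g0 == 1).sum()), int((g0 == 0).sum())],
            [int((g1 == 1).sum()), int((g1 == 0).sum())],
        ]
        p = fisher_exact_2x2(table)
        return {"test": "fisher-exact", "table": table, "p": p}
    u, p = mann_whitney(g0.to_numpy(float), g1.to_numpy(float))
    return {
        "test": "mann-whitney",
        "U": u,
        "p": p,
        "mean0": float(g0.mean()),
        "mean1": float(g1.mean()),
        "n0": int(g0.size),
        "n1": int(g1.size),
    }


# ---------------------------------------------------------------------------
# power / sample size


def _point_biserial_power(n: int, rho: float, alpha: float, tails: str) -> float:
    """Power of the t-test of rho = 0 under the point-biserial model.

    The test statistic follows a noncentral t with df = n - 2 and
    noncentrality delta = rho / sqrt(1 - rho^2) * sqrt(n).
    """
    df = n - 2
    nc = rho / np.sqrt(1.0 - rho**2) * np.sqrt(n)
    if tails == "one":
        tcrit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(tcrit, df, nc))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def sample_size_point_biserial(spec: PowerSpec, n_max: int = 10_000_000) -> int:
    """Smallest total n reaching the requested power for a point-biserial
    correlation test of rho = 0.

    Power is computed from the noncentral t distribution; the search
    exploits monotonicity of power in n (doubling then bisection).
    Raises if the power is unattainable below ``n_max``.
    """
    lo = 4
    if _point_biserial_power(lo, spec.rho, spec.alpha, spec.tails) >= spec.power:
        return lo
    hi = 8
    while _point_biserial_power(hi, spec.rho, spec.alpha, spec.tails) < spec.power:
        hi *= 2
        if hi > n_max:
            raise GroupStatsError(
                f"requested power {spec.power} unattainable below n={n_max}"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _point_biserial_power(mid, spec.rho, spec.alpha, spec.tails) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi
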