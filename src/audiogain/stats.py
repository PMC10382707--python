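"""Two-tailed statistical battery: rank tests, Spearman, t tests, ANOVA+LSD.

Each routine returns a :class:`StatResult` carrying the named test, the
statistic, degrees of freedom, the two-tailed p value and per-group
summaries.  Branch points between exact enumeration and large-sample
approximations are explicit:

* rank-sum — exact enumeration when ``min(n_a, n_b) <= 8`` and no ties,
  otherwise normal approximation with tie and continuity corrections;
* signed-rank — zeros dropped, exact sign enumeration for ``n <= 12``,
  otherwise normal approximation;
* Spearman — exact permutation enumeration for ``n <= 10``, otherwise the
  t approximation;
* unpaired t — pooled-variance (Student) form, matching the classical
  one-way ANOVA / LSD machinery;
* one-way ANOVA followed by Fisher's LSD pairwise tests (unadjusted,
  gate-kept on omnibus significance).

All tests are two-tailed with alpha = 0.05 unless overridden.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "LsdComparison",
    "AnovaLsdResult",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "spearman",
    "t_tests",
    "anova_lsd",
    "bootstrap_median_ci",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class StatResult:
    test: str
    statistic: float
    p: float
    df: Optional[tuple] = None
    method: Optional[str] = None  # "exact" | "asymptotic" | closed form
    group_summaries: list = field(default_factory=list)
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p value {self.p} outside [0, 1]")


def _summary(name: str, x: np.ndarray) -> dict:
    return {
        "group": name,
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
    }


# ---------------------------------------------------------------- rank-sum


def _ranksum_exact_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Exact two-tailed p for the rank-sum W of group a by full enumeration
    of group-label assignments over the (mid)ranks."""
    n = len(ranks)
    total = 0
    lo = 0
    hi = 0
    w_obs = round(w_obs, 10)
    for combo in itertools.combinations(range(n), n_a):
        w = round(float(ranks[list(combo)].sum()), 10)
        total += 1
        if w <= w_obs:
            lo += 1
        if w >= w_obs:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_rank_sum(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    method: str = "auto",
) -> StatResult:
    """Two-sample Wilcoxon rank-sum test on medians.

    ``method="auto"`` uses exact enumeration when ``min(n_a, n_b) <= 8`` and
    the pooled data contain no ties, else a normal approximation with
    midrank tie correction and continuity correction.  The statistic
    reported is W, the rank sum of ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    n_a, n_b = a.size, b.size
    w = float(ranks[:n_a].sum())
    has_ties = np.unique(pooled).size < pooled.size

    if method == "auto":
        method = "exact" if (min(n_a, n_b) <= 8 and not has_ties) else "asymptotic"
    if method == "exact":
        p = _ranksum_exact_p(ranks, n_a, w)
    elif method == "asymptotic":
        n = n_a + n_b
        mu = n_a * (n + 1) / 2.0
        # Tie correction on the rank variance.
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            p = 1.0
        else:
            z = (w - mu - math.copysign(0.5, w - mu)) / math.sqrt(var)
            if w == mu:
                z = 0.0
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")

    return StatResult(
        test="wilcoxon_rank_sum",
        statistic=w,
        p=p,
        method=method,
        group_summaries=[_summary("a", a), _summary("b", b)],
        extra={"n_a": n_a, "n_b": n_b, "ties": bool(has_ties)},
    )


# ------------------------------------------------------------- signed-rank


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-tailed p for W+ by full 2^n sign enumeration."""
    n = len(ranks)
    total = 2**n
    lo = hi = 0
    w_obs = round(w_obs, 10)
    for mask in range(total):
        w = round(
            float(sum(ranks[i] for i in range(n) if (mask >> i) & 1)), 10
        )
        if w <= w_obs:
            lo += 1
        if w >= w_obs:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_signed_rank(
    differences: Sequence[float],
    method: str = "auto",
    zero_method: str = "wilcox",
) -> StatResult:
    """Paired Wilcoxon signed-rank test on a vector of differences.

    Zeros are dropped before ranking (``zero_method="wilcox"``; ``"pratt"``
    keeps them in the ranking but excludes them from the statistic).  Exact
    enumeration of the 2^n sign assignments is used for ``n <= 12``,
    otherwise a normal approximation with tie correction.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference vector")
    if np.all(d == 0):
        logger.warning("all paired differences are zero; returning p = 1")
        return StatResult(
            test="wilcoxon_signed_rank",
            statistic=0.0,
            p=1.0,
            method="degenerate",
            group_summaries=[_summary("differences", d)],
        )

    if zero_method == "wilcox":
        dz = d[d != 0]
        ranks = sps.rankdata(np.abs(dz))
    elif zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        keep = d != 0
        dz = d[keep]
        ranks = ranks_all[keep]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")

    n = dz.size
    w_plus = float(ranks[dz > 0].sum())

    if method == "auto":
        method = "exact" if n <= 12 else "asymptotic"
    if method == "exact":
        p = _signed_rank_exact_p(ranks, w_plus)
    elif method == "asymptotic":
        mu = float(ranks.sum()) / 2.0
        # variance with midrank ties: sum(r^2)/4
        var = float(np.sum(ranks**2)) / 4.0
        if var == 0:
            p = 1.0
        else:
            z = (w_plus - mu - math.copysign(0.5, w_plus - mu)) / math.sqrt(var)
            if w_plus == mu:
                z = 0.0
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")

    return StatResult(
        test="wilcoxon_signed_rank",
        statistic=w_plus,
        p=p,
        method=method,
        group_summaries=[_summary("differences", d)],
        extra={"n_nonzero": int(n), "n_zero": int(np.sum(d == 0))},
    )


# ---------------------------------------------------------------- spearman


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("constant input; Spearman rho undefined")
    return float(rx @ ry) / denom


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
) -> StatResult:
    """Spearman rank correlation: Pearson correlation of midranks.

    p by full n! permutation enumeration for ``n <= 10``, else the t
    approximation ``t = rho * sqrt((n-2) / (1 - rho^2))`` on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)

    if method == "auto":
        method = "exact" if n <= 10 else "asymptotic"
    if method == "exact":
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(rxc @ ryc[list(perm)]) / denom
            total += 1
            if abs(r) >= target:
                count += 1
        p = count / total
        df = None
    elif method == "asymptotic":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2))
        df = (n - 2,)
    else:
        raise ValueError(f"unknown method {method!r}")

    return StatResult(
        test="spearman",
        statistic=rho,
        p=p,
        df=df,
        method=method,
        extra={"n": int(n)},
    )


# ----------------------------------------------------------------- t tests


def t_tests(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    paired: bool = False,
) -> StatResult:
    """Student t test: pooled-variance unpaired form, or paired on differences.

    Degenerate zero-variance data with equal means return p = 1 (logged).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        if a.size < 2:
            raise ValueError("need >= 2 pairs")
        d = a - b
        if np.std(d, ddof=1) == 0:
            if np.mean(d) == 0:
                logger.warning("zero-variance equal-mean paired data; p = 1")
                return StatResult(
                    test="paired_t", statistic=0.0, p=1.0, df=(a.size - 1,),
                    method="degenerate",
                    group_summaries=[_summary("a", a), _summary("b", b)],
                )
            raise ValueError("constant nonzero differences: t undefined")
        t, p = sps.ttest_rel(a, b)
        df = (a.size - 1,)
        name = "paired_t"
    else:
        if a.size < 2 or b.size < 2:
            raise ValueError("need >= 2 observations per group")
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                logger.warning("zero-variance equal-mean groups; p = 1")
                return StatResult(
                    test="unpaired_t", statistic=0.0, p=1.0,
                    df=(a.size + b.size - 2,), method="degenerate",
                    group_summaries=[_summary("a", a), _summary("b", b)],
                )
            raise ValueError("zero within-group variance, unequal means")
        t, p = sps.ttest_ind(a, b, equal_var=True)
        df = (a.size + b.size - 2,)
        name = "unpaired_t"
    return StatResult(
        test=name,
        statistic=float(t),
        p=float(p),
        df=df,
        method="student",
        group_summaries=[_summary("a", a), _summary("b", b)],
    )


# -------------------------------------------------------------- ANOVA + LSD


@dataclass
class LsdComparison:
    group_i: str
    group_j: str
    mean_diff: float
    t: float
    df: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass
class AnovaLsdResult:
    anova: StatResult
    lsd: list  # of LsdComparison; empty when gate-kept
    lsd_run: bool


def anova_lsd(
    groups: dict,
    alpha: float = ALPHA,
    always_posthoc: bool = False,
) -> AnovaLsdResult:
    """Ordinary one-way ANOVA followed by Fisher's LSD pairwise tests.

    ``groups`` maps label -> sample.  LSD pairwise t tests use the pooled
    within-group mean square on N-k df, with no multiplicity adjustment,
    and run only when the omnibus p < alpha (override with
    ``always_posthoc``).
    """
    labels = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    k = len(data)
    if k < 2:
        raise ValueError("need >= 2 groups")
    for g, x in zip(labels, data):
        if x.size < 2:
            raise ValueError(f"group {g!r} has < 2 observations")
    ns = np.array([x.size for x in data])
    N = int(ns.sum())
    grand = float(np.concatenate(data).mean())
    means = np.array([x.mean() for x in data])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((x - x.mean()) ** 2) for x in data))
    df_b, df_w = k - 1, N - k
    ms_between = ss_between / df_b
    msw = ss_within / df_w
    if msw == 0:
        if ss_between == 0:
            f, p = 0.0, 1.0
        else:
            raise ValueError("zero within-group variance, unequal means")
    else:
        f = ms_between / msw
        p = float(sps.f.sf(f, df_b, df_w))

    anova = StatResult(
        test="one_way_anova",
        statistic=float(f),
        p=p,
        df=(df_b, df_w),
        method="closed_form",
        alpha=alpha,
        group_summaries=[_summary(g, x) for g, x in zip(labels, data)],
        extra={"ms_within": msw, "ss_between": ss_between, "ss_within": ss_within},
    )

    lsd_run = always_posthoc or (p < alpha and k >= 3)
    comparisons: list[LsdComparison] = []
    if lsd_run and msw > 0:
        for i, j in itertools.combinations(range(k), 2):
            diff = float(means[i] - means[j])
            se = math.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]))
            t = diff / se
            p_ij = min(1.0, 2.0 * float(sps.t.sf(abs(t), df=df_w)))
            comparisons.append(
                LsdComparison(
                    group_i=labels[i], group_j=labels[j],
                    mean_diff=diff, t=t, df=df_w, p=p_ij,
                )
            )
    return AnovaLsdResult(anova=anova, lsd=comparisons, lsd_run=bool(lsd_run and msw > 0))


# ----------------------------------------------------------- bootstrap CI


def bootstrap_median_ci(
    x: Sequence[float],
    n_boot: int = 10_000,
    conf: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the median (construction labelled as such)."""
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    lo = (1.0 - conf) / 2.0
    return (
        float(np.quantile(meds, lo)),
        float(np.quantile(meds, 1.0 - lo)),
    )
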