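"""Univariate statistical primitives for group comparisons.

Implements the decision-rule toolkit used on each biomarker: a single-pass
2-SD outlier filter, a Monte-Carlo-calibrated Kolmogorov-Smirnov normality
test (Lilliefors construction: mean and SD estimated from the sample),
one-way ANOVA with Fisher's LSD planned contrasts, Welch's t, Mann-Whitney
U, the Benjamini-Krieger-Yekutieli two-stage adaptive FDR, pooled-SD
Cohen's d, post-hoc power from the noncentral t distribution, and Pearson
correlation.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "remove_outliers_2sd",
    "ks_normality",
    "anova_fisher_lsd",
    "welch_t",
    "mann_whitney_u",
    "bky_fdr",
    "cohens_d",
    "posthoc_power",
    "pearson_r",
    "proportional_volume",
    "levene_equal_var",
]

_KS_NULL_SIMS = 10_000
_KS_NULL_SEED = 20_210_831  # fixed: identical inputs give identical p


def remove_outliers_2sd(values: Sequence[float]) -> tuple[np.ndarray, list[int]]:
    """Drop values more than 2 sample SDs from the sample mean.

    A single pass: the mean and SD (ddof=1) are computed once from the full
    input and every value with ``|x - mean| > 2*SD`` is removed; order is
    preserved. With zero SD (all values identical) nothing is removed.

    Returns
    -------
    filtered : ndarray
        The retained values, in input order.
    removed : list of int
        Indices (into the input) of the removed values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for outlier screening")
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy(), []
    keep = np.abs(x - x.mean()) <= 2 * sd
    return x[keep], list(np.nonzero(~keep)[0])


def _lilliefors_statistic(z: np.ndarray) -> float:
    """KS distance of standardized, sorted data from the standard normal."""
    n = z.shape[-1]
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    dplus = (i / n - cdf).max(axis=-1)
    dminus = (cdf - (i - 1) / n).max(axis=-1)
    return np.maximum(dplus, dminus)


@lru_cache(maxsize=64)
def _ks_null_table(n: int) -> np.ndarray:
    """Monte-Carlo null distribution of the estimated-parameter KS statistic."""
    rng = np.random.default_rng(_KS_NULL_SEED)
    draws = rng.standard_normal((_KS_NULL_SIMS, n))
    draws.sort(axis=1)
    z = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(axis=1, ddof=1, keepdims=True)
    null = _lilliefors_statistic(z)
    null.sort()
    return null


def ks_normality(values: Sequence[float]) -> float:
    """Composite-normality KS test p-value (Monte-Carlo calibrated).

    The KS statistic is computed against a normal with the sample's own
    mean and SD; because estimating the parameters shrinks the statistic,
    the naive KS p-value is anti-conservative, so the null distribution is
    simulated (10^4 standard-normal samples of the same size, fixed
    internal seed, cached per sample size).
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 5:
        raise ValueError("need at least 5 values for the normality test")
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    z = (x - x.mean()) / sd
    stat = float(_lilliefors_statistic(z))
    null = _ks_null_table(x.size)
    exceed = null.size - np.searchsorted(null, stat, side="left")
    return float((1 + exceed) / (1 + null.size))


class ContrastTest(NamedTuple):
    statistic: float
    df: float
    p_value: float


def anova_fisher_lsd(
    groups: Sequence[Sequence[float]],
    contrasts: Sequence[tuple[int, int]],
) -> tuple[float, list[ContrastTest]]:
    """One-way ANOVA with Fisher's LSD tests on planned contrasts.

    The omnibus F is computed over all groups; each planned pairwise
    contrast (a, b), given as group indices, is tested with the LSD
    statistic t = (mean_a - mean_b) / sqrt(MSE * (1/n_a + 1/n_b)) on
    N - k degrees of freedom. Planned contrasts are reported regardless
    of the omnibus result.

    Returns the omnibus p-value and one :class:`ContrastTest` per contrast.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(gs)
    n_total = sum(g.size for g in gs)
    df_err = n_total - k
    sse = sum(((g - g.mean()) ** 2).sum() for g in gs)
    mse = sse / df_err
    if mse == 0:
        raise ValueError("zero within-group variance (MSE = 0)")
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    f_stat = (ssb / (k - 1)) / mse
    omnibus_p = float(sps.f.sf(f_stat, k - 1, df_err))

    out = []
    for a, b in contrasts:
        ga, gb = gs[a], gs[b]
        t = (ga.mean() - gb.mean()) / np.sqrt(mse * (1 / ga.size + 1 / gb.size))
        p = 2 * sps.t.sf(abs(t), df_err)
        out.append(ContrastTest(float(t), float(df_err), float(p)))
    return omnibus_p, out


def welch_t(a: Sequence[float], b: Sequence[float]) -> ContrastTest:
    """Welch's unequal-variance t test with Satterthwaite df (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return ContrastTest(0.0, float(a.size + b.size - 2), 1.0)
        raise ValueError("zero variance in both groups")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.size**2 * (a.size - 1)) + vb**2 / (b.size**2 * (b.size - 1)))
    p = 2 * sps.t.sf(abs(t), df)
    return ContrastTest(float(t), float(df), float(p))


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when min(n) <= 8 and the pooled data
    have no ties, and the tie-corrected normal approximation (with
    continuity correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 values per group")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bky_fdr(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, dict]:
    """Benjamini-Krieger-Yekutieli two-stage adaptive step-up FDR.

    Stage 1 runs Benjamini-Hochberg at q' = q / (1 + q) and counts r1
    rejections, giving the null-count estimate m0_hat = m - r1. If r1 = 0
    nothing is rejected; if r1 = m everything is; otherwise stage 2 reruns
    BH at level q' * m / m0_hat and its rejections are final.

    Returns
    -------
    reject : bool ndarray, same order as the input
    diagnostics : dict with ``r1`` and ``m0_hat``
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), {"r1": 0, "m0_hat": 0}
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    q1 = q / (1 + q)
    r1 = _bh_reject_count(p, q1)
    if r1 == 0:
        return np.zeros(m, dtype=bool), {"r1": 0, "m0_hat": m}
    if r1 == m:
        return np.ones(m, dtype=bool), {"r1": m, "m0_hat": 0}
    m0_hat = m - r1
    q2 = q1 * m / m0_hat
    r2 = _bh_reject_count(p, q2)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    reject[order[:r2]] = True
    return reject, {"r1": int(r1), "m0_hat": int(m0_hat)}


def _bh_reject_count(p: np.ndarray, q: float) -> int:
    """Number of Benjamini-Hochberg step-up rejections at level q."""
    m = p.size
    p_sorted = np.sort(p)
    below = p_sorted <= q * np.arange(1, m + 1) / m
    return int(np.nonzero(below)[0][-1] + 1) if below.any() else 0


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Pooled-SD standardized mean difference, (mean_a - mean_b)/s_pooled.

    ``s_pooled^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)``.
    Antisymmetric under swapping the groups; a d of 1 means the group
    means differ by one pooled standard deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def posthoc_power(d: float, n_a: int, n_b: int, alpha: float = 0.05) -> float:
    """Post-hoc power of the two-sided two-sample t test at effect size d.

    Noncentrality ncp = d * sqrt(n_a n_b / (n_a + n_b)) on
    df = n_a + n_b - 2; power = P(|T| > t_crit) under the noncentral t.
    At d = 0 this equals alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    df = n_a + n_b - 2
    ncp = d * np.sqrt(n_a * n_b / (n_a + n_b))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    return float(power)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def proportional_volume(roi_volume: float, total_brain_volume: float) -> float:
    """ROI volume as a fraction of total brain volume (both in mm^3)."""
    if roi_volume <= 0 or total_brain_volume <= 0:
        raise ValueError("volumes must be positive")
    return roi_volume / total_brain_volume


def levene_equal_var(a: Sequence[float], b: Sequence[float]) -> float:
    """p-value of the two-group F-ratio test of equal variances.

    The larger sample variance goes in the numerator; two-sided p from
    the F distribution. Used to dispatch between the pooled-variance LSD
    test and Welch's t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if va >= vb:
        f, d1, d2 = (va / vb if vb > 0 else np.inf), a.size - 1, b.size - 1
    else:
        f, d1, d2 = vb / va, b.size - 1, a.size - 1
    if np.isinf(f):
        return 0.0
    return float(min(1.0, 2 * sps.f.sf(f, d1, d2)))
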