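"""Per-kindred power under the negative-binomial segregation model.

The test statistic is the mean tumor multiplicity of a kindred of n
progeny, referred to its null normal approximation:

    H0:  Ybar ~ N(mu, (mu + mu^2/k) / n)

Under the alternative a modifier of fold f segregates to each animal
with probability s (default 1/2), so a single count is the two-point
mixture over carrier status and

    E[Ybar]   = mu * (1 - s + s f)
    Var[Ybar] = [ s (f mu + (f mu)^2/k) + (1-s)(mu + mu^2/k)
                  + s(1-s) mu^2 (f-1)^2 ] / n ,

the last term being the between-genotype variance contributed by
segregation itself. Power is the alternative-normal mass beyond the null
critical values. The default test is two-sided at alpha = 0.05;
one-sided versions serve enhancer-only or suppressor-only screens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "DesignQuery",
    "kindred_mean_distribution",
    "kindred_power",
    "progeny_for_power",
    "neutrality_test",
]


@dataclass(frozen=True)
class DesignQuery:
    """One power query: colony NB parameters, fold effect, cluster size."""

    fold_effect: float
    progeny: int
    mean: float = 99.8
    shape: float = 9.8
    alpha: float = 0.05
    sided: str = "two"
    segregation: float = 0.5

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.shape <= 0 or self.fold_effect <= 0:
            raise ValueError("mean, shape and fold_effect must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")
        if not 0.0 < self.segregation <= 1.0:
            raise ValueError("segregation must be in (0, 1]")


def kindred_mean_distribution(
    q: DesignQuery, under_alternative: bool
) -> tuple[float, float]:
    """(mean, sd) of the kindred average under H0 or the segregating
    alternative."""
    if q.progeny < 1:
        raise ValueError("progeny must be >= 1")
    mu, k, n, s, f = q.mean, q.shape, q.progeny, q.segregation, q.fold_effect
    var0 = mu + mu * mu / k
    if not under_alternative:
        return mu, float(np.sqrt(var0 / n))
    fm = f * mu
    var1 = s * (fm + fm * fm / k) + (1.0 - s) * var0 + s * (1.0 - s) * mu * mu * (f - 1.0) ** 2
    return mu * (1.0 - s + s * f), float(np.sqrt(var1 / n))


def _critical_values(q: DesignQuery) -> tuple[float, float]:
    """(lower, upper) rejection cutoffs for the kindred mean; one-sided
    tests place all mass on the side the fold effect points to."""
    m0, sd0 = kindred_mean_distribution(q, under_alternative=False)
    if q.sided == "two":
        z = stats.norm.ppf(1.0 - q.alpha / 2.0)
        return m0 - z * sd0, m0 + z * sd0
    z = stats.norm.ppf(1.0 - q.alpha)
    if q.fold_effect >= 1.0:
        return -np.inf, m0 + z * sd0
    return m0 - z * sd0, np.inf


def kindred_power(q: DesignQuery, method: str = "stratified") -> float:
    """Probability the kindred mean falls in the rejection region.

    ``method='stratified'`` (default) conditions on the binomial carrier
    count and applies the normal approximation within each stratum —
    markedly more accurate for small clusters, where the marginal
    distribution of the mean is a visibly non-normal mixture.
    ``method='marginal'`` uses the single normal with the between-genotype
    variance folded in (the moments of
    :func:`kindred_mean_distribution`).
    """
    lo, hi = _critical_values(q)
    if method == "marginal":
        m1, sd1 = kindred_mean_distribution(q, under_alternative=True)
        return float(stats.norm.cdf(lo, m1, sd1) + stats.norm.sf(hi, m1, sd1))
    if method != "stratified":
        raise ValueError("method must be 'stratified' or 'marginal'")
    mu, k, n, s, f = q.mean, q.shape, q.progeny, q.segregation, q.fold_effect
    fm = f * mu
    var0 = mu + mu * mu / k
    var_f = fm + fm * fm / k
    b = np.arange(n + 1)
    pb = stats.binom.pmf(b, n, s)
    m_b = ((n - b) * mu + b * fm) / n
    sd_b = np.sqrt(((n - b) * var0 + b * var_f)) / n
    reject_b = stats.norm.cdf(lo, m_b, sd_b) + stats.norm.sf(hi, m_b, sd_b)
    return float(np.dot(pb, reject_b))


def progeny_for_power(
    q: DesignQuery, power_target: float = 0.9, max_progeny: int = 100_000
) -> int:
    """Smallest cluster size reaching ``power_target``.

    The returned n satisfies power(n) >= target > power(n - 1). Raises
    for a null fold effect (the target is unreachable) or if no n up to
    ``max_progeny`` suffices.
    """
    if q.fold_effect == 1.0:
        raise ValueError("fold_effect = 1 carries no signal; power cannot exceed alpha")
    if not 0.0 < power_target < 1.0:
        raise ValueError("power_target must be in (0, 1)")
    lo, hi = 1, 1
    while kindred_power(replace(q, progeny=hi)) < power_target:
        lo = hi
        hi *= 2
        if hi > max_progeny:
            raise ValueError(f"no cluster size up to {max_progeny} reaches the target")
    while lo < hi:
        mid = (lo + hi) // 2
        if kindred_power(replace(q, progeny=mid)) >= power_target:
            hi = mid
        else:
            lo = mid + 1
    return hi


def neutrality_test(counts_a, counts_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value for equal count distributions.

    Used to check that a candidate mapping-partner line does not itself
    modify the tumor phenotype. Exact when there are no ties.
    """
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
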