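"""Phenotype density models shared by the mixture and power machinery.

The screen is analysed on one of two channels behind one interface:

* tumor multiplicity — negative binomial NB(mean, shape), variance
  mean + mean^2/shape; a modifier fold ``f`` multiplies the mean and leaves
  the shape untouched;
* log-lifespan — Normal, with a fold ``f`` on tumor count shifting mean
  log-lifespan by ``-slope * log(f)`` through the survival link.

Both expose baseline and fold-shifted log-densities plus sampling, so the
mixture likelihood and the Monte-Carlo oracles never special-case the
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln


@dataclass
class NegativeBinomialPhenotype:
    """NB(mean, shape) tumor-count model; fold scales the mean only."""

    mean: float = 99.8
    shape: float = 9.8
    _const_cache: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.shape <= 0:
            raise ValueError("mean and shape must be positive")

    def _p(self, fold):
        return self.shape / (self.shape + np.asarray(fold) * self.mean)

    def logpdf(self, y, fold: float = 1.0) -> np.ndarray:
        y = np.asarray(y)
        if np.any(y < 0):
            raise ValueError("tumor counts must be non-negative")
        return stats.nbinom.logpmf(y, self.shape, self._p(fold))

    def _count_const(self, y: np.ndarray) -> np.ndarray:
        # gammaln(y + k) - gammaln(k) - gammaln(y + 1), cached per count
        # vector: it is the only expensive part of the pmf and does not
        # depend on the fold. The cache keeps a reference to the keyed
        # array so identity comparison stays valid.
        cached = self._const_cache
        if cached is not None and cached[0] is y:
            return cached[1]
        const = gammaln(y + self.shape) - gammaln(self.shape) - gammaln(y + 1.0)
        self._const_cache = (y, const)
        return const

    def fold_logpdf_matrix(self, y: np.ndarray, folds: np.ndarray) -> np.ndarray:
        """(len(y), len(folds)) matrix of log pmf at fold-scaled means."""
        y = np.asarray(y, dtype=float)
        folds = np.asarray(folds, dtype=float)
        p = self._p(folds)
        const = self._count_const(y)
        return (
            const[:, None]
            + self.shape * np.log(p)[None, :]
            + y[:, None] * np.log1p(-p)[None, :]
        )

    def rvs(self, rng: np.random.Generator, size, fold=1.0) -> np.ndarray:
        return rng.negative_binomial(self.shape, self._p(fold), size=size)

    def moments(self, fold: float = 1.0) -> tuple[float, float]:
        """(mean, variance) of a single count at the given fold."""
        m = fold * self.mean
        return m, m + m * m / self.shape

    def ppf(self, q, fold: float = 1.0):
        out = stats.nbinom.ppf(q, self.shape, self._p(fold))
        return out.item() if np.ndim(out) == 0 else out

    def sf(self, x, fold: float = 1.0):
        """P(Y > x)."""
        out = stats.nbinom.sf(x, self.shape, self._p(fold))
        return out.item() if np.ndim(out) == 0 else out

    def cdf(self, x, fold: float = 1.0):
        out = stats.nbinom.cdf(x, self.shape, self._p(fold))
        return out.item() if np.ndim(out) == 0 else out


@dataclass
class GaussianLogPhenotype:
    """Normal model for log-lifespan under the survival link.

    ``mu`` and ``sigma`` describe the baseline log-lifespan; a tumor-count
    fold ``f`` shifts the mean by ``-effect_slope * log(f)`` (enhancers
    shorten life, suppressors lengthen it).
    """

    mu: float
    sigma: float
    effect_slope: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def _mean(self, fold):
        return self.mu - self.effect_slope * np.log(np.asarray(fold))

    def logpdf(self, y, fold: float = 1.0) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValueError("lifespans must be positive")
        return stats.norm.logpdf(np.log(y), self._mean(fold), self.sigma)

    def fold_logpdf_matrix(self, y: np.ndarray, folds: np.ndarray) -> np.ndarray:
        y = np.log(np.asarray(y, dtype=float))
        means = self._mean(np.asarray(folds, dtype=float))
        z = (y[:, None] - means[None, :]) / self.sigma
        return -0.5 * z * z - np.log(self.sigma) - 0.5 * np.log(2.0 * np.pi)

    def rvs(self, rng: np.random.Generator, size, fold=1.0) -> np.ndarray:
        return np.exp(rng.normal(self._mean(fold), self.sigma, size=size))

    def moments(self, fold: float = 1.0) -> tuple[float, float]:
        """(mean, variance) of the lifespan itself (log-normal moments)."""
        m = np.exp(self._mean(fold) + 0.5 * self.sigma**2)
        v = (np.exp(self.sigma**2) - 1.0) * m * m
        return float(m), float(v)

    def ppf(self, q: float, fold: float = 1.0) -> float:
        return float(np.exp(stats.norm.ppf(q, self._mean(fold), self.sigma)))

    def sf(self, x: float, fold: float = 1.0) -> float:
        return float(stats.norm.sf(np.log(x), self._mean(fold), self.sigma))

    def cdf(self, x: float, fold: float = 1.0) -> float:
        return float(stats.norm.cdf(np.log(x), self._mean(fold), self.sigma))
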