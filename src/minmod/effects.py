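"""Distributions of multiplicative modifier fold effects.

A dominant modifier multiplies the expected tumor count by a fold ``f``:
suppressors have ``f`` in (0, 1), enhancers ``f > 1``. The package's
default family is a log-normal on ``f`` truncated to the appropriate side
of 1; a point mass and a discrete grid are provided as alternatives (the
grid also arises naturally when a continuous effect distribution is
conditioned on a kindred-selection event).

All distributions expose a small common surface: random sampling,
probability-weighted quadrature nodes for integrating a smooth function of
the fold, and tail mass beyond a fold threshold.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats


class FoldEffect(ABC):
    """Common interface for fold-effect distributions."""

    @abstractmethod
    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Sample ``size`` folds."""

    @abstractmethod
    def quadrature(self, n_nodes: int = 12) -> tuple[np.ndarray, np.ndarray]:
        """Nodes and probability weights with sum(w) = 1 such that
        ``sum(w_i g(f_i))`` approximates ``E[g(F)]`` for smooth ``g``."""

    @abstractmethod
    def tail_prob(self, threshold: float) -> float:
        """P(F >= threshold) if threshold > 1 else P(F <= threshold)."""


@dataclass(frozen=True)
class TruncatedLogNormalEffect(FoldEffect):
    """Log-normal fold effect truncated to (lower, upper).

    ``loc``/``scale`` are the mean and SD of log-fold before truncation.
    Suppressors use ``upper=1``, enhancers ``lower=1``.
    """

    loc: float
    scale: float
    lower: float = 0.0
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not 0.0 <= self.lower < self.upper:
            raise ValueError("require 0 <= lower < upper")

    def _bounds(self) -> tuple[float, float]:
        a = -np.inf if self.lower == 0.0 else (np.log(self.lower) - self.loc) / self.scale
        b = np.inf if np.isinf(self.upper) else (np.log(self.upper) - self.loc) / self.scale
        return a, b

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a, b = self._bounds()
        z = stats.truncnorm.rvs(a, b, size=size, random_state=rng)
        return np.exp(self.loc + self.scale * z)

    def quadrature(self, n_nodes: int = 12) -> tuple[np.ndarray, np.ndarray]:
        # Gauss-Legendre in quantile space: nodes are truncated-normal
        # quantiles of the Legendre abscissae mapped to (0, 1).
        a, b = self._bounds()
        x, w = leggauss(n_nodes)
        u = 0.5 * (x + 1.0)
        z = stats.truncnorm.ppf(u, a, b)
        return np.exp(self.loc + self.scale * z), 0.5 * w

    def tail_prob(self, threshold: float) -> float:
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        a, b = self._bounds()
        z = (np.log(threshold) - self.loc) / self.scale
        if threshold > 1.0:
            return float(stats.truncnorm.sf(z, a, b))
        return float(stats.truncnorm.cdf(z, a, b))

    @classmethod
    def suppressor(cls, median: float = 0.6, log_sd: float = 0.2) -> "TruncatedLogNormalEffect":
        """Suppressor-side default: median fold 0.6, log-SD 0.2, support (0, 1)."""
        return cls(loc=float(np.log(median)), scale=log_sd, upper=1.0)

    @classmethod
    def enhancer(cls, median: float = 1.8, log_sd: float = 0.2) -> "TruncatedLogNormalEffect":
        """Enhancer-side default: median fold 1.8, log-SD 0.2, support (1, inf)."""
        return cls(loc=float(np.log(median)), scale=log_sd, lower=1.0)


@dataclass(frozen=True)
class PointMassEffect(FoldEffect):
    """A single deterministic fold effect."""

    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.fold)

    def quadrature(self, n_nodes: int = 12) -> tuple[np.ndarray, np.ndarray]:
        return np.array([self.fold]), np.array([1.0])

    def tail_prob(self, threshold: float) -> float:
        if threshold > 1.0:
            return float(self.fold >= threshold)
        return float(self.fold <= threshold)


class DiscreteEffect(FoldEffect):
    """Fold effect on a finite grid with given probabilities."""

    def __init__(self, folds, probs) -> None:
        folds = np.asarray(folds, dtype=float)
        probs = np.asarray(probs, dtype=float)
        if folds.shape != probs.shape or folds.ndim != 1 or folds.size == 0:
            raise ValueError("folds and probs must be matching non-empty 1-d arrays")
        if np.any(folds <= 0) or np.any(probs < 0):
            raise ValueError("folds must be positive and probs non-negative")
        total = probs.sum()
        if total <= 0:
            raise ValueError("probs must have positive mass")
        self.folds = folds
        self.probs = probs / total

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(self.folds, size=size, p=self.probs)

    def quadrature(self, n_nodes: int = 12) -> tuple[np.ndarray, np.ndarray]:
        return self.folds, self.probs

    def tail_prob(self, threshold: float) -> float:
        if threshold > 1.0:
            return float(self.probs[self.folds >= threshold].sum())
        return float(self.probs[self.folds <= threshold].sum())
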