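"""Screen-size design under the FDR-nonempty discovery criterion.

A screen phenotypes N kindreds of n progeny each. Per-kindred p-values
come from the null normal approximation of the kindred mean (the same
approximation as :mod:`minmod.power`), the list of reported kindreds is
controlled by Benjamini-Hochberg at q (default 5%), and the design asks
for the smallest N such that the reported list contains at least one
kindred truly carrying a modifier beyond an effect threshold with
probability >= the discovery target (default 95%). The probability is
evaluated by Monte Carlo over whole screens, with common random numbers
across candidate N so the estimated discovery curve is monotone and the
doubling-plus-bisection search on N is well behaved.

Preselection (extreme-kindred enrichment) plugs in by conditioning the
kindred mixture on the selection event and re-running the same design
machinery on the enriched mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .enrichment import SelectionRule, selection_conditional_mixture
from .mixture import MixtureParams
from .phenotype import NegativeBinomialPhenotype
from .power import DesignQuery, kindred_mean_distribution
from .rng import substream

__all__ = [
    "ScreenDesign",
    "bh_reject",
    "discovery_probability",
    "screen_size_for_discovery",
    "preselected_design",
]


@dataclass(frozen=True)
class ScreenDesign:
    """Design targets plus the kindred mixture assumed for the colony."""

    mixture: MixtureParams
    baseline: NegativeBinomialPhenotype = field(default_factory=NegativeBinomialPhenotype)
    fdr_q: float = 0.05
    discovery_prob: float = 0.95
    power_target: float = 0.9

    def __post_init__(self) -> None:
        for name in ("fdr_q", "discovery_prob", "power_target"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


def bh_reject(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask, vectorised over rows.

    ``pvalues`` is (n_screens, n_tests); each row is one screen's batch
    of per-kindred p-values.
    """
    p = np.atleast_2d(np.asarray(pvalues, dtype=float))
    n_rows, n = p.shape
    order = np.argsort(p, axis=1)
    p_sorted = np.take_along_axis(p, order, axis=1)
    thresh = q * np.arange(1, n + 1) / n
    ok = p_sorted <= thresh[None, :]
    any_ok = ok.any(axis=1)
    kmax = np.where(any_ok, n - 1 - np.argmax(ok[:, ::-1], axis=1), -1)
    reject_sorted = np.arange(n)[None, :] <= kmax[:, None]
    reject = np.zeros_like(ok)
    np.put_along_axis(reject, order, reject_sorted, axis=1)
    if np.asarray(pvalues).ndim == 1:
        return reject[0]
    return reject


class _ScreenDraws:
    """Lazily grown common-random-number pool of simulated kindreds.

    Column j of every array describes kindred slot j in all replicate
    screens, so evaluating N and N' > N uses the same kindreds for the
    first N slots.
    """

    def __init__(self, design: ScreenDesign, n_progeny: int, mc_reps: int, seed: int):
        self.design = design
        self.n_progeny = n_progeny
        self.mc_reps = mc_reps
        self.rng = substream(seed, "screen_design")
        self.classes = np.empty((mc_reps, 0), dtype=np.int8)
        self.folds = np.empty((mc_reps, 0))
        self.pvalues = np.empty((mc_reps, 0))

    def _sample_block(self, n_cols: int):
        d, rng = self.design, self.rng
        mix = d.mixture
        shape = (self.mc_reps, n_cols)
        classes = rng.choice(3, size=shape, p=np.asarray(mix.weights)).astype(np.int8)
        folds = np.ones(shape)
        for idx, effect in ((1, mix.suppressor), (2, mix.enhancer)):
            mask = classes == idx
            n_draw = int(mask.sum())
            if n_draw:
                folds[mask] = effect.rvs(rng, n_draw)
        # kindred means from the normal approximation, then two-sided
        # p-values against the null approximation
        q0 = DesignQuery(
            fold_effect=1.0, progeny=self.n_progeny,
            mean=d.baseline.mean, shape=d.baseline.shape,
            segregation=mix.segregation,
        )
        m0, sd0 = kindred_mean_distribution(q0, under_alternative=False)
        # vectorised alternative moments (same formulas as kindred_mean_distribution)
        mu, k, s = d.baseline.mean, d.baseline.shape, mix.segregation
        var0 = mu + mu * mu / k
        fm = folds * mu
        var1 = s * (fm + fm * fm / k) + (1.0 - s) * var0 + s * (1.0 - s) * mu * mu * (folds - 1.0) ** 2
        m1 = mu * (1.0 - s + s * folds)
        s1 = np.sqrt(var1 / self.n_progeny)
        means = m1 + s1 * rng.standard_normal(shape)
        z = np.abs(means - m0) / sd0
        pvals = 2.0 * stats.norm.sf(z)
        return classes, folds, pvals

    def ensure(self, n_cols: int) -> None:
        have = self.pvalues.shape[1]
        if n_cols <= have:
            return
        classes, folds, pvals = self._sample_block(n_cols - have)
        self.classes = np.concatenate((self.classes, classes), axis=1)
        self.folds = np.concatenate((self.folds, folds), axis=1)
        self.pvalues = np.concatenate((self.pvalues, pvals), axis=1)

    def discovery_probability(self, n_kindreds: int, effect_threshold: float) -> float:
        self.ensure(n_kindreds)
        p = self.pvalues[:, :n_kindreds]
        rejected = bh_reject(p, self.design.fdr_q)
        folds = self.folds[:, :n_kindreds]
        if effect_threshold > 1.0:
            is_big = (self.classes[:, :n_kindreds] == 2) & (folds >= effect_threshold)
        else:
            is_big = (self.classes[:, :n_kindreds] == 1) & (folds <= effect_threshold)
        hit = (rejected & is_big).any(axis=1)
        return float(hit.mean())


def _check_effect_mass(mixture: MixtureParams, effect_threshold: float) -> None:
    pi0, pi_s, pi_e = mixture.weights
    if effect_threshold > 1.0:
        mass = pi_e * mixture.enhancer.tail_prob(effect_threshold)
    elif 0.0 < effect_threshold < 1.0:
        mass = pi_s * mixture.suppressor.tail_prob(effect_threshold)
    else:
        raise ValueError("effect_threshold must be positive and differ from 1")
    if mass <= 0.0:
        raise ValueError(
            f"the mixture has zero modifier mass beyond fold {effect_threshold}; "
            "no screen size can meet the discovery target"
        )


def discovery_probability(
    design: ScreenDesign,
    n_kindreds: int,
    n_progeny: int,
    effect_threshold: float,
    mc_reps: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo P(BH list contains a true modifier beyond threshold)."""
    _check_effect_mass(design.mixture, effect_threshold)
    draws = _ScreenDraws(design, n_progeny, mc_reps, seed)
    return draws.discovery_probability(n_kindreds, effect_threshold)


def screen_size_for_discovery(
    design: ScreenDesign,
    n_progeny: int,
    effect_threshold: float,
    mc_reps: int = 2000,
    seed: int = 0,
    max_kindreds: int = 1_000_000,
) -> int:
    """Smallest N with discovery probability >= the design target.

    Searches by doubling then bisection over N, reusing one common pool
    of simulated kindreds for all candidate N.
    """
    if mc_reps < 1000:
        raise ValueError("mc_reps must be at least 1000 for a stable design")
    _check_effect_mass(design.mixture, effect_threshold)
    draws = _ScreenDraws(design, n_progeny, mc_reps, seed)
    target = design.discovery_prob
    hi = 1
    while draws.discovery_probability(hi, effect_threshold) < target:
        hi *= 2
        if hi > max_kindreds:
            raise ValueError(f"no screen size up to {max_kindreds} meets the target")
    lo = max(1, hi // 2)
    while lo < hi:
        mid = (lo + hi) // 2
        if draws.discovery_probability(mid, effect_threshold) >= target:
            hi = mid
        else:
            lo = mid + 1
    return hi


def preselected_design(
    design: ScreenDesign,
    rule: SelectionRule,
    n_progeny: int,
    effect_threshold: float,
    mc_reps: int = 2000,
    seed: int = 0,
) -> tuple[int, int]:
    """(number of selected kindreds, progeny each) meeting the discovery
    target when only kindreds passing the selection rule are phenotyped.

    The kindred mixture is conditioned on the selection event (classes
    reweighted, effect distributions tilted toward folds that survive
    selection) and the screen-size search runs on the enriched mixture.
    """
    enriched = selection_conditional_mixture(design.mixture, design.baseline, rule)
    enriched_design = ScreenDesign(
        mixture=enriched,
        baseline=design.baseline,
        fdr_q=design.fdr_q,
        discovery_prob=design.discovery_prob,
        power_target=design.power_target,
    )
    n_sel = screen_size_for_discovery(
        enriched_design, n_progeny, effect_threshold, mc_reps=mc_reps, seed=seed
    )
    return n_sel, n_progeny
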