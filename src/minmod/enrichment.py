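"""Enrichment of large modifier effects by extreme-kindred selection.

Screening kindreds whose clusters contain multiple animals with extreme
phenotypes (very short- or long-lived, i.e. very high or low tumor
counts) enriches the selected set for kindreds carrying large-effect
modifiers. With "extreme" defined as a baseline tail of mass q, an
animal of a modifier kindred with fold f is extreme with probability

    p(f) = s * P(Y_f in tail) + (1 - s) * P(Y_0 in tail),

(s = segregation probability), and a cluster of c animals is selected
when at least m are extreme — a binomial tail in p(f). Integrating the
selection event over the class/effect mixture gives

    enrichment = P(effect beyond threshold | selected)
                 / P(effect beyond threshold).

The same machinery yields the selection-conditioned mixture used to
design a screen restricted to preselected kindreds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .effects import DiscreteEffect
from .mixture import MixtureParams
from .phenotype import NegativeBinomialPhenotype


@dataclass(frozen=True)
class SelectionRule:
    """Select kindreds with >= ``min_extreme`` of ``cluster_size`` animals
    in the baseline tail of mass ``extreme_quantile``.

    ``tail='upper'`` flags high tumor counts (short-lived animals, the
    enhancer side); ``tail='lower'`` the suppressor side.
    ``min_extreme=0`` is the vacuous rule that selects every kindred.

    Counts are discrete, so the tail is defined inclusively against the
    baseline quantile: extreme means Y > threshold for the upper tail
    and Y <= threshold for the lower tail, with the threshold at the
    (1-q) / q baseline quantile respectively.
    """

    min_extreme: int
    cluster_size: int
    extreme_quantile: float = 0.05
    tail: str = "upper"

    def __post_init__(self) -> None:
        if not 0 <= self.min_extreme <= self.cluster_size:
            raise ValueError("require 0 <= min_extreme <= cluster_size")
        if not 0.0 < self.extreme_quantile <= 0.5:
            raise ValueError("extreme_quantile must be in (0, 0.5]")
        if self.tail not in ("upper", "lower"):
            raise ValueError("tail must be 'upper' or 'lower'")

    def threshold(self, baseline: NegativeBinomialPhenotype) -> float:
        """Baseline phenotype cutoff defining 'extreme'."""
        if self.tail == "upper":
            return baseline.ppf(1.0 - self.extreme_quantile)
        return baseline.ppf(self.extreme_quantile)

    def extreme_prob(self, baseline: NegativeBinomialPhenotype, fold) -> np.ndarray:
        """P(one animal at the given fold is extreme); exact NB tail mass,
        so discreteness of the count distribution is respected."""
        t = self.threshold(baseline)
        fold = np.atleast_1d(np.asarray(fold, dtype=float))
        if self.tail == "upper":
            p = np.array([baseline.sf(t, f) for f in fold])
        else:
            p = np.array([baseline.cdf(t, f) for f in fold])
        return p

    def selection_prob(
        self, baseline: NegativeBinomialPhenotype, fold, segregation: float
    ) -> np.ndarray:
        p0 = float(self.extreme_prob(baseline, 1.0)[0])
        pf = self.extreme_prob(baseline, fold)
        per_animal = segregation * pf + (1.0 - segregation) * p0
        return stats.binom.sf(self.min_extreme - 1, self.cluster_size, per_animal)

    def null_selection_prob(self, baseline: NegativeBinomialPhenotype) -> float:
        p0 = float(self.extreme_prob(baseline, 1.0)[0])
        return float(stats.binom.sf(self.min_extreme - 1, self.cluster_size, p0))


def _class_terms(
    params: MixtureParams,
    baseline: NegativeBinomialPhenotype,
    rule: SelectionRule,
    n_quad: int,
):
    """Per-class quadrature folds, probability weights and selection probs."""
    out = {}
    for name, effect in (("suppressor", params.suppressor), ("enhancer", params.enhancer)):
        folds, w = effect.quadrature(n_quad)
        psel = rule.selection_prob(baseline, folds, params.segregation)
        out[name] = (folds, w, psel)
    return out


def extreme_selection_enrichment(
    params: MixtureParams,
    baseline: NegativeBinomialPhenotype,
    rule: SelectionRule,
    large_effect_threshold: float,
    n_quad: int = 24,
) -> float:
    """P(effect beyond threshold | selected) / P(effect beyond threshold).

    ``large_effect_threshold`` > 1 asks about enhancer folds >= threshold;
    < 1 about suppressor folds <= threshold. Raises if the selection
    event or the large-effect event has zero probability under the model.
    """
    if large_effect_threshold == 1.0:
        raise ValueError("large_effect_threshold must differ from 1")
    pi0, pi_s, pi_e = params.weights
    terms = _class_terms(params, baseline, rule, n_quad)

    def beyond(folds: np.ndarray) -> np.ndarray:
        if large_effect_threshold > 1.0:
            return folds >= large_effect_threshold
        return folds <= large_effect_threshold

    p_big = 0.0
    p_sel = pi0 * rule.null_selection_prob(baseline)
    p_big_and_sel = 0.0
    for pi_c, name in ((pi_s, "suppressor"), (pi_e, "enhancer")):
        folds, w, psel = terms[name]
        mask = beyond(folds)
        p_big += pi_c * float(w[mask].sum())
        p_sel += pi_c * float(np.dot(w, psel))
        p_big_and_sel += pi_c * float(np.dot(w[mask], psel[mask]))
    if p_sel <= 0.0:
        raise ValueError(
            f"selection event has zero probability (rule={rule}); "
            "no kindred can satisfy it under this model"
        )
    if p_big <= 0.0:
        raise ValueError(
            f"no effect mass beyond fold {large_effect_threshold} in the mixture"
        )
    return (p_big_and_sel / p_sel) / p_big


def selection_conditional_mixture(
    params: MixtureParams,
    baseline: NegativeBinomialPhenotype,
    rule: SelectionRule,
    n_quad: int = 24,
) -> MixtureParams:
    """The mixture over kindreds *conditioned on passing the selection rule*.

    Class weights are reweighted by each class's selection probability and
    the continuous effect distributions become discrete grids reweighted
    by P(selected | fold). Used by the preselected screen design.
    """
    pi0, pi_s, pi_e = params.weights
    terms = _class_terms(params, baseline, rule, n_quad)
    mass0 = pi0 * rule.null_selection_prob(baseline)
    new = {}
    masses = {"none": mass0}
    for pi_c, name in ((pi_s, "suppressor"), (pi_e, "enhancer")):
        folds, w, psel = terms[name]
        wsel = w * psel
        mass = float(wsel.sum())
        masses[name] = pi_c * mass
        if mass > 0:
            new[name] = DiscreteEffect(folds, wsel)
        else:
            new[name] = DiscreteEffect(folds, w)
    total = sum(masses.values())
    if total <= 0.0:
        raise ValueError("selection event has zero probability under this model")
    return MixtureParams(
        weights=(masses["none"] / total, masses["suppressor"] / total, masses["enhancer"] / total),
        suppressor=new["suppressor"],
        enhancer=new["enhancer"],
        segregation=params.segregation,
    )
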