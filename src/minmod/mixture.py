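"""Maximum-likelihood estimation of the segregating modifier mixture.

Model
-----
Each kindred k independently draws a latent class c from
(pi_0, pi_s, pi_e) = (unaffected, suppressor, enhancer). A modifier
kindred additionally draws one fold effect f from its class's effect
distribution G_c; each of its progeny inherits the modifier with
probability s (default 1/2, Mendelian segregation of a heterozygous G1
founder). Given class, fold and the baseline phenotype density p0, the
kindred likelihood is

    L_k(c) = E_{f ~ G_c} prod_j [ s * p(y_kj | f) + (1 - s) * p0(y_kj) ]

for modifier classes (carriers and non-carriers mix within the kindred),
and prod_j p0(y_kj) for the unaffected class; the marginal likelihood is
sum_c pi_c L_k(c). The expectation over f is evaluated by Gauss-Legendre
quadrature in quantile space of G_c.

Fitting is by ECM: class responsibilities give closed-form weight
updates; each effect component's (location, scale) is improved by a
bounded Nelder-Mead conditional step accepted only when it increases the
objective, so the log-likelihood path is non-decreasing by construction.
The suppressor component is constrained to folds in (0, 1) and the
enhancer to (1, inf) by truncation, which pins the labels.

The effect family here is the truncated log-normal; this likelihood is a
reconstruction of the screening model from its published summary (the
original's exact effect family is not public) and is documented as such
in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .effects import FoldEffect, TruncatedLogNormalEffect
from .phenotype import NegativeBinomialPhenotype
from .rng import substream

CLASS_NAMES = ("none", "suppressor", "enhancer")

_SCALE_BOUNDS = (1e-3, 2.0)


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the segregating three-component mixture.

    The effect components may be any :class:`~minmod.effects.FoldEffect`;
    fitting uses truncated log-normals, while selection-conditioned
    mixtures carry discrete grids.
    """

    weights: tuple[float, float, float]
    suppressor: FoldEffect
    enhancer: FoldEffect
    segregation: float = 0.5

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or np.any(w < -1e-12):
            raise ValueError("weights must be three non-negative numbers")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {w.sum():.12f}, not 1")


@dataclass
class MixtureFit:
    """Result of :func:`fit_mixture`."""

    params: MixtureParams
    baseline: NegativeBinomialPhenotype
    log_likelihood: float
    loglik_path: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    n_quad: int = 12

    @property
    def weights(self) -> tuple[float, float, float]:
        return self.params.weights


class _KindredData:
    """Flattened cohort: counts grouped contiguously by kindred."""

    def __init__(self, kindred_counts: list[np.ndarray]):
        if any(len(c) == 0 for c in kindred_counts):
            raise ValueError("every kindred needs at least one animal")
        arrays = [np.asarray(c, dtype=float) for c in kindred_counts]
        if any(np.any(a < 0) for a in arrays):
            raise ValueError("phenotype values must be non-negative")
        self.y = np.concatenate(arrays) if arrays else np.array([])
        sizes = np.array([len(a) for a in arrays], dtype=int)
        self.starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        self.n_kindreds = len(arrays)


def _modifier_class_ll(
    data: _KindredData,
    model: NegativeBinomialPhenotype,
    effect,
    segregation: float,
    n_quad: int,
    base: np.ndarray,
) -> np.ndarray:
    """(K,) log-likelihood of one modifier class, integrating over its folds."""
    log_s = np.log(segregation)
    log_1ms = np.log1p(-segregation) if segregation < 1 else -np.inf
    folds, w = effect.quadrature(n_quad)
    lp = model.fold_logpdf_matrix(data.y, folds)  # (A, Q)
    per_animal = np.logaddexp(lp + log_s, base[:, None] + log_1ms)
    per_kq = np.add.reduceat(per_animal, data.starts, axis=0)  # (K, Q)
    return logsumexp(per_kq + np.log(w)[None, :], axis=1)


def _class_logliks(
    data: _KindredData,
    model: NegativeBinomialPhenotype,
    params: MixtureParams,
    n_quad: int,
    base_ll_k: np.ndarray | None = None,
) -> np.ndarray:
    """(K, 3) per-kindred log-likelihood for each latent class."""
    base = model.logpdf(data.y)
    if base_ll_k is None:
        base_ll_k = np.add.reduceat(base, data.starts)
    out = np.empty((data.n_kindreds, 3))
    out[:, 0] = base_ll_k
    out[:, 1] = _modifier_class_ll(data, model, params.suppressor, params.segregation, n_quad, base)
    out[:, 2] = _modifier_class_ll(data, model, params.enhancer, params.segregation, n_quad, base)
    return out


def kindred_loglik(
    counts,
    params: MixtureParams,
    baseline: NegativeBinomialPhenotype,
    n_quad: int = 12,
) -> float:
    """Marginal log-likelihood of one kindred under the mixture."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("kindred must contain at least one animal")
    data = _KindredData([counts])
    ll = _class_logliks(data, baseline, params, n_quad)[0]
    w = np.asarray(params.weights, dtype=float)
    with np.errstate(divide="ignore"):
        return float(logsumexp(ll + np.log(w)))


def posterior_class(
    counts,
    fit: MixtureFit,
) -> np.ndarray:
    """Posterior P(class | kindred) = (none, suppressor, enhancer); sums to 1."""
    data = _KindredData([np.asarray(counts)])
    ll = _class_logliks(data, fit.baseline, fit.params, fit.n_quad)[0]
    with np.errstate(divide="ignore"):
        logpost = ll + np.log(np.asarray(fit.weights, dtype=float))
    logpost -= logsumexp(logpost)
    return np.exp(logpost)


def _moment_init(
    data: _KindredData,
    model: NegativeBinomialPhenotype,
    rng: np.random.Generator,
    perturb: bool,
    margin: float = 0.1,
) -> MixtureParams:
    """Method-of-moments start from the trimmed tails of kindred means."""
    sizes = np.diff(np.concatenate((data.starts, [len(data.y)])))
    means = np.add.reduceat(data.y, data.starts) / sizes
    mu, var1 = model.moments()
    sd = np.sqrt(var1 / sizes)
    z = (means - mu) / sd
    pi_e = np.clip(2.0 * np.mean(z > 2.0), 0.05, 0.6)
    pi_s = np.clip(2.0 * np.mean(z < -2.0), 0.05, 0.6)
    if pi_e + pi_s > 0.9:
        scale = 0.9 / (pi_e + pi_s)
        pi_e, pi_s = pi_e * scale, pi_s * scale

    def tail_fold(mask, lo, hi):
        if mask.sum() >= 3:
            f = 2.0 * np.mean(means[mask]) / mu - 1.0
            return float(np.clip(f, lo, hi))
        return float(np.sqrt(lo * hi))

    f_s = tail_fold(z < -2.0, 0.2, 0.95)
    f_e = tail_fold(z > 2.0, 1.1, 4.0)
    loc_s, loc_e, scale_s, scale_e = np.log(f_s), np.log(f_e), 0.3, 0.3
    if perturb:
        loc_s += rng.normal(0.0, 0.3)
        loc_e += rng.normal(0.0, 0.3)
        scale_s *= np.exp(rng.normal(0.0, 0.4))
        scale_e *= np.exp(rng.normal(0.0, 0.4))
        dir_w = rng.dirichlet(10.0 * np.array([1.0 - pi_s - pi_e, pi_s, pi_e]) + 0.5)
        pi_s, pi_e = dir_w[1], dir_w[2]
    scale_s = float(np.clip(scale_s, *_SCALE_BOUNDS))
    scale_e = float(np.clip(scale_e, *_SCALE_BOUNDS))
    return MixtureParams(
        weights=(1.0 - pi_s - pi_e, float(pi_s), float(pi_e)),
        suppressor=TruncatedLogNormalEffect(
            float(min(loc_s, -0.01)), scale_s, upper=1.0 - margin
        ),
        enhancer=TruncatedLogNormalEffect(
            float(max(loc_e, 0.01)), scale_e, lower=1.0 + margin
        ),
    )


def _em(
    data: _KindredData,
    model: NegativeBinomialPhenotype,
    params: MixtureParams,
    tol: float,
    max_iter: int,
    n_quad: int,
    weight_floor: float = 1e-10,
    cm_maxfev: int = 25,
) -> MixtureFit:
    base = model.logpdf(data.y)
    base_ll_k = np.add.reduceat(base, data.starts)
    ll_path: list[float] = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        L = _class_logliks(data, model, params, n_quad, base_ll_k)
        with np.errstate(divide="ignore"):
            joint = L + np.log(np.asarray(params.weights, dtype=float))[None, :]
        norm = logsumexp(joint, axis=1)
        ll = float(norm.sum())
        ll_path.append(ll)
        resp = np.exp(joint - norm[:, None])

        # CM step 1: closed-form weights
        w = resp.mean(axis=0)
        w = np.clip(w, weight_floor, None)
        w /= w.sum()

        # CM step 2: effect parameters, one component at a time,
        # accepted only on improvement (keeps the ascent monotone)
        new_effects = {}
        for col, name in ((1, "suppressor"), (2, "enhancer")):
            effect: TruncatedLogNormalEffect = getattr(params, name)
            r = resp[:, col]
            if r.sum() < 1e-8:
                new_effects[name] = effect
                continue

            def objective(theta, _eff=effect, _r=r):
                loc, log_scale = theta
                scale = float(np.exp(log_scale))
                if not _SCALE_BOUNDS[0] <= scale <= _SCALE_BOUNDS[1]:
                    return np.inf
                trial = replace(_eff, loc=float(loc), scale=scale)
                Lc = _modifier_class_ll(
                    data, model, trial, params.segregation, n_quad, base
                )
                return -float(np.dot(_r, Lc))

            x0 = np.array([effect.loc, np.log(effect.scale)])
            f0 = objective(x0)
            res = minimize(
                objective, x0, method="Nelder-Mead",
                options={"maxfev": cm_maxfev, "xatol": 1e-4, "fatol": 1e-7},
            )
            if res.fun < f0:
                new_effects[name] = replace(
                    effect, loc=float(res.x[0]), scale=float(np.exp(res.x[1]))
                )
            else:
                new_effects[name] = effect

        params = MixtureParams(
            weights=tuple(w),
            suppressor=new_effects["suppressor"],
            enhancer=new_effects["enhancer"],
            segregation=params.segregation,
        )
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(ll) + 1.0):
            converged = True
            break
        prev_ll = ll

    # final log-likelihood at the returned parameters
    L = _class_logliks(data, model, params, n_quad, base_ll_k)
    with np.errstate(divide="ignore"):
        final_ll = float(
            logsumexp(L + np.log(np.asarray(params.weights))[None, :], axis=1).sum()
        )
    ll_path.append(final_ll)
    return MixtureFit(
        params=params,
        baseline=model,
        log_likelihood=final_ll,
        loglik_path=ll_path,
        n_iterations=it,
        converged=converged,
        n_quad=n_quad,
    )


def fit_mixture(
    kindred_counts: list,
    baseline: NegativeBinomialPhenotype,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int = 0,
    n_quad: int = 12,
    screen_tol: float = 1e-6,
    screen_max_iter: int = 400,
    segregation: float = 0.5,
    effect_margin: float = 0.1,
) -> MixtureFit:
    """Fit the segregating mixture to a kindred cohort.

    ``kindred_counts`` is a sequence of per-kindred phenotype arrays (or
    :class:`minmod.simulate.Kindred` objects). Restarts run from a
    method-of-moments start plus random perturbations at the looser
    ``screen_tol``; the best restart is polished at ``tol``. Returns the
    highest-likelihood fit; a fit that hits ``max_iter`` is returned with
    ``converged=False`` rather than raising.

    ``effect_margin`` separates the fitted effect supports from fold 1
    (suppressors in (0, 1 - margin], enhancers in [1 + margin, inf)): a
    modifier of fold exactly 1 is indistinguishable from no modifier, so
    without the margin the class weights are unidentifiable on null
    data. The margin is the smallest effect the fit considers a modifier.
    """
    counts = [
        k.tumor_counts if hasattr(k, "tumor_counts") else np.asarray(k)
        for k in kindred_counts
    ]
    if len(counts) < 2:
        raise ValueError("need at least two kindreds to fit the mixture")
    data = _KindredData(counts)
    rng = substream(seed, "mixture_fit")
    candidates: list[MixtureFit] = []
    for r in range(max(1, n_restarts)):
        init = _moment_init(data, baseline, rng, perturb=r > 0, margin=effect_margin)
        init = replace(init, segregation=segregation)
        fit = _em(data, baseline, init, screen_tol, screen_max_iter, n_quad)
        candidates.append(fit)
    best = max(candidates, key=lambda f: f.log_likelihood)
    polished = _em(data, baseline, best.params, tol, max_iter, n_quad)
    polished.loglik_path = best.loglik_path[:-1] + polished.loglik_path
    return polished
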