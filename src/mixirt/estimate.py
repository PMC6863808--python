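"""Marginal maximum likelihood estimation of mixture adjacent-category models.

Estimation follows the two-stage scheme common for these models: a stable
generalized EM algorithm (posteriors over latent class x quadrature node in
the E-step; closed-form class sizes and one damped Newton step per parameter
block in the M-step), followed by a quasi-Newton refinement of the marginal
log-likelihood.  Standard errors come from the observed information matrix,
obtained by central finite differences of the analytic score (an outer
product of gradients alternative is available).

The analytic score uses Fisher's identity: the gradient of the marginal
log-likelihood equals the posterior-expected complete-data score, so the
same sufficient statistics drive the M-step, the refinement stage and the
information matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .model import (
    ModelSpec,
    ParameterSet,
    QuadratureGrid,
    build_quadrature,
    class_proportions,
    log_prob_table,
    pattern_loglik,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "ParamBlocks",
    "fit_em",
    "refine_newton",
    "multi_start_fit",
    "compute_standard_errors",
    "posterior_classification",
    "diagnose_solution",
    "random_start",
    "pack_parameters",
    "unpack_parameters",
    "n_free_parameters",
    "loglik_and_score",
]

logger = logging.getLogger(__name__)

_MONOTONE_SLACK = 1e-8
_SD_FLOOR = 1e-4
_DISC_FLOOR = 1e-3
_LOGIT_BOUND = 30.0
_SE_BOUNDARY_CUTOFF = 1e4


@dataclass
class FitConfig:
    """Estimation settings.

    Defaults mirror a conservative production setup: EM capped at 10,000
    iterations with an absolute log-likelihood-change tolerance of 0.01,
    Newton refinement capped at 600 iterations with a scaled gradient
    max-norm tolerance of 1e-8, 100 start sets of 200 EM iterations each,
    and 80 Gauss-Hermite quadrature points.
    """

    em_max_iter: int = 10_000
    em_tol: float = 0.01
    nr_max_iter: int = 600
    nr_tol: float = 1e-8
    n_starts: int = 100
    start_em_iter: int = 200
    n_quadrature: int = 80
    warm_start: Optional[ParameterSet] = None
    se_method: str = "observed_information"
    delta_bound: float = 50.0
    quadrature_kind: str = "gauss_hermite"
    #: smoothing weight: one pseudo-observation per item response table,
    #: spread over classes and distributed over categories in proportion to
    #: the item's observed marginal distribution, plus one over the class
    #: sizes — the reference software's default Bayes constants.  0 = pure ML.
    prior_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.em_tol <= 0 or self.nr_tol <= 0:
            raise ValueError("tolerances must be positive")
        if min(self.em_max_iter, self.nr_max_iter, self.n_starts,
               self.start_em_iter) < 1:
            raise ValueError("iteration caps must be positive")

    def grid(self) -> QuadratureGrid:
        return build_quadrature(self.n_quadrature, self.quadrature_kind)


@dataclass
class ParamBlocks:
    """Parameter-shaped container without model invariants (SEs, flags)."""

    delta_beta: np.ndarray
    item_discrimination: np.ndarray
    trait_scale: np.ndarray
    class_logit: np.ndarray

    def copy(self) -> "ParamBlocks":
        return ParamBlocks(*(np.copy(a) for a in (
            self.delta_beta, self.item_discrimination,
            self.trait_scale, self.class_logit)))


@dataclass
class FitResult:
    """One fitted class solution."""

    spec: ModelSpec
    params: ParameterSet
    loglik: float
    objective: float
    n_free_parameters: int
    em_converged: bool
    em_iterations: int
    nr_converged: bool = False
    nr_iterations: int = 0
    standard_errors: Optional[ParamBlocks] = None
    se_boundary: Optional[ParamBlocks] = None
    param_boundary: Optional[ParamBlocks] = None
    improper: bool = False
    degenerate_class: bool = False
    posterior: Optional[np.ndarray] = None
    mean_assignment_probability: float = np.nan
    loglik_path: list = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# free-parameter vector

def _free_layout(spec: ModelSpec):
    g, i, s = spec.n_classes, spec.n_items, spec.n_categories - 1
    n_delta = g * i * s
    n_disc = 0 if spec.equal_discrimination else i - 1
    return n_delta, n_disc, g, g - 1


def n_free_parameters(spec: ModelSpec) -> int:
    return sum(_free_layout(spec))


def pack_parameters(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Flatten free coordinates: delta-betas, discriminations (items 2..I,
    rmGPCM only), trait scales, class logits (classes 2..G)."""
    parts = [params.delta_beta.ravel()]
    if not spec.equal_discrimination:
        parts.append(params.item_discrimination[1:])
    parts.append(params.trait_scale)
    parts.append(params.class_logit[1:])
    return np.concatenate(parts)


def unpack_parameters(theta: np.ndarray, spec: ModelSpec) -> ParameterSet:
    g, i, s = spec.n_classes, spec.n_items, spec.n_categories - 1
    n_delta, n_disc, n_scale, n_logit = _free_layout(spec)
    pos = 0
    delta = theta[pos:pos + n_delta].reshape(g, i, s).copy()
    pos += n_delta
    disc = np.ones(i)
    if n_disc:
        disc[1:] = theta[pos:pos + n_disc]
        pos += n_disc
    scale = theta[pos:pos + n_scale].copy()
    pos += n_scale
    logit = np.zeros(g)
    if n_logit:
        logit[1:] = theta[pos:pos + n_logit]
    return ParameterSet(delta, disc, scale, logit)


# ---------------------------------------------------------------------------
# E-step and sufficient statistics

def _trait_sd(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    if spec.trait_scale_is_variance:
        return np.sqrt(np.maximum(params.trait_scale, 0.0))
    return params.trait_scale


def _estep(params: ParameterSet, responses: np.ndarray, grid: QuadratureGrid,
           spec: ModelSpec):
    """Marginal log-likelihood and joint posteriors over (class, node)."""
    joint = pattern_loglik(params, responses, grid,
                           spec.trait_scale_is_variance)
    ll_v = logsumexp(joint, axis=(1, 2))
    if not np.all(np.isfinite(ll_v)):
        raise FloatingPointError("non-finite marginal likelihood in E-step")
    post = np.exp(joint - ll_v[:, None, None])
    return float(ll_v.sum()), post


def _one_hot(responses: np.ndarray, n_categories: int) -> np.ndarray:
    n, i = responses.shape
    out = np.zeros((i, n, n_categories))
    rows = np.arange(n)
    for j in range(i):
        out[j, rows, responses[:, j]] = 1.0
    return out


def _expected_counts(post: np.ndarray, one_hot: np.ndarray) -> np.ndarray:
    """Posterior-expected category counts, shape (G, Q, I, C)."""
    n, g, q = post.shape
    flat = post.reshape(n, g * q)
    i, _, c = one_hot.shape
    counts = np.empty((g * q, i, c))
    for j in range(i):
        counts[:, j, :] = flat.T @ one_hot[j]
    return counts.reshape(g, q, i, c)


def _tail_sums(arr: np.ndarray) -> np.ndarray:
    """Reverse cumulative sums over the category axis, steps 1..C-1."""
    rev = np.cumsum(arr[..., ::-1], axis=-1)[..., ::-1]
    return rev[..., 1:]


# ---------------------------------------------------------------------------
# smoothing prior (posterior-mode analogue of the reference software's
# default Bayes constants)

def _observed_margins(one_hot: np.ndarray) -> np.ndarray:
    """Observed marginal category proportions per item, shape (I, C)."""
    return one_hot.mean(axis=1)


def _prior_pseudocounts(spec: ModelSpec, grid: QuadratureGrid, alpha: float,
                        margins: np.ndarray) -> np.ndarray:
    """Pseudo-counts (G, Q, I, C): ``alpha`` observations per item response
    table, spread over classes and the trait grid and distributed over
    categories in proportion to the item's observed marginal distribution."""
    g = spec.n_classes
    return (alpha / g) * (grid.weights[None, :, None, None]
                          * margins[None, None, :, :]
                          * np.ones((g, 1, 1, 1)))


def _prior_value(params: ParameterSet, spec: ModelSpec, grid: QuadratureGrid,
                 alpha: float, margins: np.ndarray | None) -> float:
    if alpha == 0.0:
        return 0.0
    logp = log_prob_table(params, grid.nodes, spec.trait_scale_is_variance)
    pseudo = _prior_pseudocounts(spec, grid, alpha, margins)
    pi = class_proportions(params.class_logit)
    return float((pseudo * logp).sum()
                 + (alpha / spec.n_classes) * np.log(pi).sum())


# ---------------------------------------------------------------------------
# score (Fisher identity) — shared by refinement and information matrix

def _score_blocks(params: ParameterSet, spec: ModelSpec,
                  grid: QuadratureGrid, counts: np.ndarray,
                  post_class: np.ndarray):
    """Expected complete-data score per block at the posterior ``counts``."""
    sd = _trait_sd(params, spec)
    prob = np.exp(log_prob_table(params, grid.nodes,
                                 spec.trait_scale_is_variance))
    n_gqi = counts.sum(axis=-1)
    tail_n = _tail_sums(counts)
    tail_p = _tail_sums(prob)
    grad_delta = (tail_n - n_gqi[..., None] * tail_p).sum(axis=1)

    cats = np.arange(spec.n_categories, dtype=float)
    mean_cat = prob @ cats
    resid = counts @ cats - n_gqi * mean_cat            # (G, Q, I)
    trait = sd[:, None] * grid.nodes[None, :]           # (G, Q)
    grad_disc = np.einsum("gq,gqi->i", trait, resid)
    grad_sd = np.einsum("q,i,gqi->g", grid.nodes,
                        params.item_discrimination, resid)
    if spec.trait_scale_is_variance:
        grad_scale = grad_sd / (2.0 * np.maximum(sd, _SD_FLOOR))
    else:
        grad_scale = grad_sd
    pi = class_proportions(params.class_logit)
    grad_logit = post_class - post_class.sum() * pi
    return grad_delta, grad_disc, grad_scale, grad_logit


def loglik_and_score(theta: np.ndarray, responses: np.ndarray,
                     spec: ModelSpec, grid: QuadratureGrid, one_hot=None,
                     prior_strength: float = 0.0):
    """Objective (marginal log-likelihood plus smoothing prior, if any) and
    its gradient over free parameters."""
    params = unpack_parameters(theta, spec)
    ll, post = _estep(params, responses, grid, spec)
    if one_hot is None:
        one_hot = _one_hot(np.asarray(responses, dtype=np.intp),
                           spec.n_categories)
    counts = _expected_counts(post, one_hot)
    post_class = post.sum(axis=(0, 2))
    value = ll
    if prior_strength > 0.0:
        margins = _observed_margins(one_hot)
        counts = counts + _prior_pseudocounts(spec, grid, prior_strength,
                                              margins)
        post_class = post_class + prior_strength / spec.n_classes
        value += _prior_value(params, spec, grid, prior_strength, margins)
    gd, gdisc, gscale, glogit = _score_blocks(params, spec, grid, counts,
                                              post_class)
    parts = [gd.ravel()]
    if not spec.equal_discrimination:
        parts.append(gdisc[1:])
    parts.append(gscale)
    parts.append(glogit[1:])
    return value, np.concatenate(parts)


# ---------------------------------------------------------------------------
# M-step block updates (generalized EM: one damped Newton step per block)

def _block_value(delta: np.ndarray, offset: np.ndarray,
                 counts: np.ndarray) -> float:
    """Expected complete-data log-likelihood of one (class, item) slice."""
    s = delta.size
    eta = np.zeros((offset.size, s + 1))
    eta[:, 1:] = np.cumsum(delta[None, :] + offset[:, None], axis=1)
    logp = eta - logsumexp(eta, axis=1, keepdims=True)
    return float((counts * logp).sum())


def _probs_for_block(delta: np.ndarray, offset: np.ndarray) -> np.ndarray:
    s = delta.size
    eta = np.zeros((offset.size, s + 1))
    eta[:, 1:] = np.cumsum(delta[None, :] + offset[:, None], axis=1)
    logp = eta - logsumexp(eta, axis=1, keepdims=True)
    return np.exp(logp)


def _update_delta_block(delta: np.ndarray, offset: np.ndarray,
                        counts: np.ndarray, bound: float) -> np.ndarray:
    """One damped Newton step on the delta-betas of one (class, item)."""
    n_q = counts.sum(axis=1)
    prob = _probs_for_block(delta, offset)
    tail_p = _tail_sums(prob)
    tail_n = _tail_sums(counts)
    grad = (tail_n - n_q[:, None] * tail_p).sum(axis=0)
    s = delta.size
    idx = np.maximum.outer(np.arange(s), np.arange(s))
    joint = np.einsum("q,qst->st", n_q, tail_p[:, idx])
    outer = (tail_p * n_q[:, None]).T @ tail_p
    hess = -(joint - outer)
    try:
        step = np.linalg.solve(-hess + 1e-10 * np.eye(s), grad)
    except np.linalg.LinAlgError:
        step = grad / max(n_q.sum(), 1.0)
    base = _block_value(delta, offset, counts)
    alpha = 1.0
    for _ in range(25):
        cand = np.clip(delta + alpha * step, -bound, bound)
        if _block_value(cand, offset, counts) >= base - 1e-12:
            return cand
        alpha *= 0.5
    return delta


def _update_scalar(value: float, coef: np.ndarray, counts2d: np.ndarray,
                   delta_cum: np.ndarray, lo: float, hi: float) -> float:
    """Damped Newton step for one scalar whose step-logit coefficient is
    ``coef[k]`` per row: eta[k, c] = delta_cum[k, c] + c * coef[k] * value."""
    cats = np.arange(counts2d.shape[1], dtype=float)

    def probs(v):
        eta = delta_cum + cats[None, :] * coef[:, None] * v
        return np.exp(eta - logsumexp(eta, axis=1, keepdims=True))

    def qval(v):
        eta = delta_cum + cats[None, :] * coef[:, None] * v
        logp = eta - logsumexp(eta, axis=1, keepdims=True)
        return float((counts2d * logp).sum())

    p = probs(value)
    n_k = counts2d.sum(axis=1)
    mu = p @ cats
    var = p @ cats**2 - mu**2
    resid = counts2d @ cats - n_k * mu
    grad = float(coef @ resid)
    hess = -float((coef**2 * n_k) @ var)
    step = grad / max(-hess, 1e-12)
    base = qval(value)
    alpha = 1.0
    for _ in range(25):
        cand = float(np.clip(value + alpha * step, lo, hi))
        if qval(cand) >= base - 1e-12:
            return cand
        alpha *= 0.5
    return value


def _mstep(params: ParameterSet, spec: ModelSpec, grid: QuadratureGrid,
           counts: np.ndarray, post_class: np.ndarray,
           bound: float) -> ParameterSet:
    g_, q_, i_, c_ = counts.shape
    delta = params.delta_beta.copy()
    disc = params.item_discrimination.copy()
    sd = _trait_sd(params, spec).copy()
    nodes = grid.nodes

    # class sizes: closed-form multinomial update on the logit scale
    pi = np.maximum(post_class / post_class.sum(), 1e-12)
    logit = np.clip(np.log(pi / pi[0]), -_LOGIT_BOUND, _LOGIT_BOUND)
    logit[0] = 0.0

    # delta-beta blocks
    for g in range(g_):
        offset_base = sd[g] * nodes
        for i in range(i_):
            delta[g, i] = _update_delta_block(
                delta[g, i], disc[i] * offset_base, counts[g, :, i, :], bound)

    cats = np.arange(c_, dtype=float)
    # item discriminations (rmGPCM only; first item fixed)
    if not spec.equal_discrimination:
        trait = sd[:, None] * nodes[None, :]
        for i in range(1, i_):
            cum = np.cumsum(delta[:, i, :], axis=-1)
            delta_cum = np.zeros((g_, q_, c_))
            delta_cum[..., 1:] = cum[:, None, :]
            disc[i] = _update_scalar(
                disc[i], trait.ravel(),
                counts[:, :, i, :].reshape(g_ * q_, c_),
                delta_cum.reshape(g_ * q_, c_), _DISC_FLOOR, 1e3)

    # class trait scales
    for g in range(g_):
        cum = np.cumsum(delta[g], axis=-1)
        delta_cum = np.zeros((q_, i_, c_))
        delta_cum[..., 1:] = cum[None, :, :]
        coef = (nodes[:, None] * disc[None, :]).ravel()
        sd[g] = _update_scalar(
            sd[g], coef,
            counts[g].transpose(0, 1, 2).reshape(q_ * i_, c_),
            delta_cum.reshape(q_ * i_, c_), _SD_FLOOR, 1e2)

    scale = sd**2 if spec.trait_scale_is_variance else sd
    return ParameterSet(delta, disc, scale, logit)


# ---------------------------------------------------------------------------
# estimation drivers

def _prepare(responses, spec: ModelSpec):
    x = np.asarray(responses, dtype=np.intp)
    if x.min() < 0 or x.max() >= spec.n_categories:
        raise ValueError("responses out of the coded category range")
    return x, _one_hot(x, spec.n_categories)


def fit_em(responses, spec: ModelSpec, start: ParameterSet,
           config: FitConfig | None = None,
           max_iter: int | None = None) -> FitResult:
    """Generalized EM from one start vector.

    The marginal log-likelihood is non-decreasing across iterations (each
    M-step block update is damped to never lower the expected complete-data
    log-likelihood); the loop stops once the absolute change drops below
    ``config.em_tol`` or the iteration cap is reached.
    """
    config = config or FitConfig()
    if start.n_classes != spec.n_classes or start.n_items != spec.n_items:
        raise ValueError("start vector incompatible with the model spec")
    grid = config.grid()
    x, one_hot = _prepare(responses, spec)
    params = start.copy()
    if spec.equal_discrimination and np.any(params.item_discrimination != 1.0):
        raise ValueError("mPCM requires all discriminations fixed to 1")
    cap = config.em_max_iter if max_iter is None else max_iter
    alpha = config.prior_strength
    margins = _observed_margins(one_hot)
    pseudo = (_prior_pseudocounts(spec, grid, alpha, margins)
              if alpha > 0 else 0.0)
    obj_prev = -np.inf
    ll = np.nan
    path = []
    converged = False
    degenerate = False
    iterations = 0
    for iterations in range(1, cap + 1):
        ll, post = _estep(params, x, grid, spec)
        obj = ll + _prior_value(params, spec, grid, alpha, margins)
        if obj < obj_prev - _MONOTONE_SLACK:
            logger.warning("EM objective decreased by %.3g at iter %d",
                           obj_prev - obj, iterations)
        path.append(obj)
        if np.isfinite(obj_prev) and abs(obj - obj_prev) < config.em_tol:
            converged = True
            break
        obj_prev = obj
        counts = _expected_counts(post, one_hot) + pseudo
        post_class = post.sum(axis=(0, 2))
        if np.any(post_class < 1e-8):
            degenerate = True
        params = _mstep(params, spec, grid, counts,
                        post_class + alpha / spec.n_classes,
                        config.delta_bound)
    if not converged:
        # cap reached: refresh the objective at the last M-step update
        ll, _ = _estep(params, x, grid, spec)
        path.append(ll + _prior_value(params, spec, grid, alpha, margins))
    return FitResult(
        spec=spec, params=params, loglik=ll, objective=path[-1],
        n_free_parameters=n_free_parameters(spec),
        em_converged=converged, em_iterations=iterations,
        degenerate_class=degenerate, loglik_path=path,
    )


def refine_newton(fit: FitResult, responses,
                  config: FitConfig | None = None) -> FitResult:
    """Quasi-Newton (L-BFGS) ascent on the marginal log-likelihood.

    Never returns a solution with a lower log-likelihood than its input;
    convergence is a gradient max-norm below ``nr_tol * (1 + |loglik|)``.
    """
    config = config or FitConfig()
    spec = fit.spec
    grid = config.grid()
    x, one_hot = _prepare(responses, spec)
    theta0 = pack_parameters(fit.params, spec)

    def negative(theta):
        val, grad = loglik_and_score(theta, x, spec, grid, one_hot,
                                     config.prior_strength)
        return -val, -grad

    n_delta, n_disc, n_scale, n_logit = _free_layout(spec)
    b = config.delta_bound
    scale_lo = 0.0 if spec.trait_scale_is_variance else _SD_FLOOR
    bounds = ([(-b, b)] * n_delta + [(_DISC_FLOOR, 1e3)] * n_disc
              + [(scale_lo, 1e2)] * n_scale
              + [(-_LOGIT_BOUND, _LOGIT_BOUND)] * n_logit)
    res = minimize(negative, theta0, jac=True, method="L-BFGS-B",
                   bounds=bounds,
                   options={"maxiter": config.nr_max_iter, "ftol": 1e-13,
                            "gtol": 1e-12})
    obj_new = -res.fun
    out = fit
    if np.isfinite(obj_new) and obj_new >= fit.objective - _MONOTONE_SLACK:
        params = unpack_parameters(res.x, spec)
        raw_ll, _ = _estep(params, x, grid, spec)
        out = FitResult(
            spec=spec, params=params, loglik=raw_ll,
            objective=float(obj_new),
            n_free_parameters=fit.n_free_parameters,
            em_converged=fit.em_converged, em_iterations=fit.em_iterations,
            degenerate_class=fit.degenerate_class,
            loglik_path=fit.loglik_path,
        )
    obj, grad = loglik_and_score(pack_parameters(out.params, spec), x, spec,
                                 grid, one_hot, config.prior_strength)
    gnorm = float(np.max(np.abs(grad)))
    out.nr_iterations = int(res.nit)
    out.nr_converged = bool(gnorm < config.nr_tol * (1.0 + abs(obj)))
    return out


def random_start(spec: ModelSpec, rng: np.random.Generator) -> ParameterSet:
    """Random start vector spanning the population parameter range."""
    g, i, s = spec.n_classes, spec.n_items, spec.n_categories - 1
    delta = rng.uniform(-2.0, 2.0, size=(g, i, s))
    disc = np.ones(i)
    if not spec.equal_discrimination:
        disc[1:] = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=i - 1))
    logit = np.zeros(g)
    logit[1:] = rng.uniform(-1.0, 1.0, size=g - 1)
    scale = rng.uniform(0.1, 1.0, size=g)
    return ParameterSet(delta, disc, scale, logit)


def multi_start_fit(responses, spec: ModelSpec,
                    config: FitConfig | None = None,
                    seed: int = 0) -> FitResult:
    """Best-of-many-starts estimation.

    Runs ``start_em_iter`` EM iterations from each random start (plus the
    warm start, if configured), continues the best candidate to full EM
    convergence and then applies the Newton refinement.  Deterministic
    given ``seed``.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    starts = []
    if config.warm_start is not None:
        starts.append(config.warm_start.copy())
    while len(starts) < config.n_starts + (config.warm_start is not None):
        starts.append(random_start(spec, rng))
    best = None
    for start in starts:
        try:
            cand = fit_em(responses, spec, start, config,
                          max_iter=config.start_em_iter)
        except FloatingPointError:
            continue
        if best is None or cand.objective > best[0].objective:
            best = (cand, start)
    if best is None:
        raise RuntimeError("no start produced a finite log-likelihood")
    fit = fit_em(responses, spec, best[0].params, config)
    return refine_newton(fit, responses, config)


# ---------------------------------------------------------------------------
# standard errors, posteriors, diagnostics

def _blocks_from_vector(vec: np.ndarray, spec: ModelSpec,
                        fill=np.nan) -> ParamBlocks:
    g, i, s = spec.n_classes, spec.n_items, spec.n_categories - 1
    n_delta, n_disc, n_scale, n_logit = _free_layout(spec)
    pos = 0
    delta = np.asarray(vec[pos:pos + n_delta]).reshape(g, i, s)
    pos += n_delta
    disc = np.full(i, fill, dtype=float)
    if n_disc:
        disc[1:] = vec[pos:pos + n_disc]
        pos += n_disc
    scale = np.asarray(vec[pos:pos + n_scale], dtype=float)
    pos += n_scale
    logit = np.full(g, fill, dtype=float)
    if n_logit:
        logit[1:] = vec[pos:pos + n_logit]
    return ParamBlocks(delta.copy(), disc, scale, logit)


def _per_respondent_scores(params: ParameterSet, spec: ModelSpec,
                           grid: QuadratureGrid, responses: np.ndarray):
    """N x P matrix of per-respondent score contributions (for OPG)."""
    x = np.asarray(responses, dtype=np.intp)
    joint = pattern_loglik(params, x, grid, spec.trait_scale_is_variance)
    ll_v = logsumexp(joint, axis=(1, 2))
    post = np.exp(joint - ll_v[:, None, None])       # (N, G, Q)
    prob = np.exp(log_prob_table(params, grid.nodes,
                                 spec.trait_scale_is_variance))
    tail_p = _tail_sums(prob)                        # (G, Q, I, S)
    s_ = spec.n_categories - 1
    ind = (x[:, :, None] >= np.arange(1, s_ + 1)[None, None, :]).astype(float)
    post_g = post.sum(axis=2)                        # (N, G)
    sc_delta = (ind[:, None, :, :] * post_g[:, :, None, None]
                - np.einsum("vgq,gqis->vgis", post, tail_p))
    cats = np.arange(spec.n_categories, dtype=float)
    mu = prob @ cats                                 # (G, Q, I)
    sd = _trait_sd(params, spec)
    trait = sd[:, None] * grid.nodes[None, :]        # (G, Q)
    w_t = np.einsum("vgq,gq->vg", post, trait)       # Σ_q post·t
    mu_t = np.einsum("vgq,gq,gqi->vi", post, trait, mu)
    sc_disc = x * w_t.sum(axis=1)[:, None] - mu_t    # (N, I)
    w_z = np.einsum("vgq,q->vg", post, grid.nodes)
    mu_z = np.einsum("vgq,q,gqi,i->vg", post, grid.nodes, mu,
                     params.item_discrimination)
    sc_sd = (x @ params.item_discrimination)[:, None] * w_z - mu_z
    if spec.trait_scale_is_variance:
        sc_scale = sc_sd / (2.0 * np.maximum(sd, _SD_FLOOR))[None, :]
    else:
        sc_scale = sc_sd
    pi = class_proportions(params.class_logit)
    sc_logit = post_g - pi[None, :]
    parts = [sc_delta.reshape(x.shape[0], -1)]
    if not spec.equal_discrimination:
        parts.append(sc_disc[:, 1:])
    parts.append(sc_scale)
    parts.append(sc_logit[:, 1:])
    return np.concatenate(parts, axis=1)


def compute_standard_errors(fit: FitResult, responses,
                            config: FitConfig | None = None) -> FitResult:
    """Attach standard errors and boundary flags to a fit (in place).

    ``observed_information``: central finite differences of the analytic
    score give the Hessian of the marginal log-likelihood; SEs are the
    square roots of the diagonal of the inverse information on the free
    parameters.  ``opg``: outer product of per-respondent scores.  An SE is
    boundary-flagged when the information is not positive definite on that
    coordinate, the SE exceeds 1e4, or the parameter sits at its clamp.
    """
    config = config or FitConfig()
    spec = fit.spec
    grid = config.grid()
    x, one_hot = _prepare(responses, spec)
    theta = pack_parameters(fit.params, spec)
    p = theta.size
    if config.se_method == "opg":
        scores = _per_respondent_scores(fit.params, spec, grid, x)
        info = scores.T @ scores
    elif config.se_method == "observed_information":
        hess = np.empty((p, p))
        step = 1e-5 * (1.0 + np.abs(theta))
        for k in range(p):
            hi = theta.copy()
            hi[k] += step[k]
            lo = theta.copy()
            lo[k] -= step[k]
            _, g_hi = loglik_and_score(hi, x, spec, grid, one_hot,
                                       config.prior_strength)
            _, g_lo = loglik_and_score(lo, x, spec, grid, one_hot,
                                       config.prior_strength)
            hess[:, k] = (g_hi - g_lo) / (2.0 * step[k])
        info = -(hess + hess.T) / 2.0
    else:
        raise ValueError(f"unknown se_method: {config.se_method!r}")

    se = np.full(p, np.nan)
    bad = np.zeros(p, dtype=bool)
    # invert on the well-determined eigenspace; directions with (near-)zero
    # information mark their participating coordinates as boundary
    sym = (info + info.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    cut = np.max(np.abs(eigval)) * 1e-8 if eigval.size else 0.0
    keep = eigval > cut
    if not keep.all():
        null = eigvec[:, ~keep]
        bad |= np.abs(null).max(axis=1) > 0.5
    diag = (eigvec[:, keep] ** 2 / eigval[keep]).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ok = np.isfinite(diag) & (diag > 0) & ~bad
    se[ok] = np.sqrt(diag[ok])
    bad |= ~np.isfinite(se) | (se > _SE_BOUNDARY_CUTOFF)
    at_clamp = np.zeros(p, dtype=bool)
    n_delta, n_disc, n_scale, n_logit = _free_layout(spec)
    at_clamp[:n_delta] = np.abs(theta[:n_delta]) >= config.delta_bound - 1e-6
    bad |= at_clamp
    fit.standard_errors = _blocks_from_vector(se, spec)
    fit.se_boundary = _blocks_from_vector(bad.astype(float), spec, fill=0.0)
    fit.param_boundary = _blocks_from_vector(at_clamp.astype(float), spec,
                                             fill=0.0)
    return fit


def posterior_classification(fit: FitResult, responses,
                             config: FitConfig | None = None) -> FitResult:
    """Posterior class memberships by Bayes rule (attached in place).

    ``mean_assignment_probability`` is the average over respondents of the
    maximum posterior class probability.
    """
    config = config or FitConfig()
    joint = pattern_loglik(fit.params, responses, config.grid(),
                           fit.spec.trait_scale_is_variance)
    log_post_g = logsumexp(joint, axis=2)
    log_post_g -= logsumexp(log_post_g, axis=1, keepdims=True)
    post = np.exp(log_post_g)
    fit.posterior = post
    fit.mean_assignment_probability = float(post.max(axis=1).mean())
    return fit


def diagnose_solution(fit: FitResult):
    """Improper-solution flag: share of boundary SEs strictly above 10%."""
    if fit.se_boundary is None:
        raise ValueError("compute_standard_errors must run first")
    blocks = {
        "delta_beta": fit.se_boundary.delta_beta,
        "item_discrimination": fit.se_boundary.item_discrimination[1:]
        if not fit.spec.equal_discrimination else np.zeros(0),
        "trait_scale": fit.se_boundary.trait_scale,
        "class_logit": fit.se_boundary.class_logit[1:],
    }
    flagged = sum(float(np.nansum(b)) for b in blocks.values())
    total = sum(b.size for b in blocks.values())
    share = flagged / total if total else 0.0
    fit.improper = bool(share > 0.10)
    summary = {name: int(np.nansum(b)) for name, b in blocks.items()}
    summary["share"] = share
    return fit.improper, summary
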