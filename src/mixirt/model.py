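"""Mixture adjacent-category logit models for polytomous rating data.

Two members of the family are supported:

* the restricted mixed generalized partial credit model (rmGPCM) — item
  discriminations vary over items but are held equal across latent classes;
* the mixed partial credit model (mPCM) — all discriminations fixed to 1.

The model is parameterized on the logistic-regression (adjacent-category)
scale.  For latent class ``g``, item ``i`` and response categories coded
``0..C-1``, the log-odds of category ``c`` against ``c-1`` is::

    log P(X=c) / P(X=c-1) = delta_beta[g, i, c] + lam_i * lam_g * z

where ``z`` is a standard-normal latent trait, ``lam_i`` the item
discrimination (first item fixed to 1) and ``lam_g`` a class-specific scale
of the trait.  Class membership follows a multinomial logit with the first
class as reference.  The equivalent IRT (threshold) parameterization is
``tau[g, i, s] = -delta_beta[g, i, s] / lam_i``.

The marginal likelihood integrates the trait per class over a quadrature
grid and sums over classes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax
from scipy.stats import norm

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "QuadratureGrid",
    "build_quadrature",
    "class_proportions",
    "category_probabilities",
    "to_irt_parameters",
    "from_irt_parameters",
    "log_prob_table",
    "marginal_loglik",
    "parameter_table",
    "parameter_set_from_table",
]

#: probability floor before taking logs
PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of a mixture adjacent-category model.

    ``equal_discrimination=True`` selects the mPCM (all item discriminations
    fixed to 1); ``False`` the rmGPCM.  ``trait_scale_is_variance`` switches
    the reading of the class trait parameter from a loading/SD (default) to a
    variance.
    """

    n_items: int
    n_categories: int
    n_classes: int
    equal_discrimination: bool = False
    trait_scale_is_variance: bool = False

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")

    @property
    def n_steps(self) -> int:
        return self.n_categories - 1


@dataclass
class ParameterSet:
    """Full parameter vector of a mixture adjacent-category model.

    Attributes
    ----------
    delta_beta : (G, I, C-1) array
        Adjacent-category intercept differences, logit units.
    item_discrimination : (I,) array
        Item discriminations; first entry fixed to 1 (all 1 for the mPCM).
    trait_scale : (G,) array
        Class-specific scale of the standard-normal trait.
    class_logit : (G,) array
        Multinomial-logit class-size parameters; first entry fixed to 0.
    """

    delta_beta: np.ndarray
    item_discrimination: np.ndarray
    trait_scale: np.ndarray
    class_logit: np.ndarray

    def __post_init__(self) -> None:
        self.delta_beta = np.asarray(self.delta_beta, dtype=float)
        self.item_discrimination = np.asarray(self.item_discrimination, dtype=float)
        self.trait_scale = np.asarray(self.trait_scale, dtype=float)
        self.class_logit = np.asarray(self.class_logit, dtype=float)
        if self.delta_beta.ndim != 3:
            raise ValueError("delta_beta must be a (G, I, C-1) array")
        g, i, _ = self.delta_beta.shape
        if self.item_discrimination.shape != (i,):
            raise ValueError("item_discrimination shape inconsistent with delta_beta")
        if self.trait_scale.shape != (g,) or self.class_logit.shape != (g,):
            raise ValueError("class-indexed blocks inconsistent with delta_beta")
        if np.any(self.item_discrimination <= 0):
            raise ValueError("item discriminations must be strictly positive")
        if self.item_discrimination[0] != 1.0:
            raise ValueError("first item discrimination must be fixed to 1")
        if self.class_logit[0] != 0.0:
            raise ValueError("first class logit must be fixed to 0")

    @property
    def n_classes(self) -> int:
        return self.delta_beta.shape[0]

    @property
    def n_items(self) -> int:
        return self.delta_beta.shape[1]

    @property
    def n_categories(self) -> int:
        return self.delta_beta.shape[2] + 1

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            self.delta_beta.copy(),
            self.item_discrimination.copy(),
            self.trait_scale.copy(),
            self.class_logit.copy(),
        )

    def spec(self, **overrides) -> ModelSpec:
        base = ModelSpec(
            n_items=self.n_items,
            n_categories=self.n_categories,
            n_classes=self.n_classes,
            equal_discrimination=bool(np.all(self.item_discrimination == 1.0)),
        )
        return replace(base, **overrides) if overrides else base

    def permute_classes(self, perm) -> "ParameterSet":
        """Return a copy with latent classes reordered by ``perm``.

        ``perm[k]`` is the old class placed at new position ``k``.  Class
        logits are re-referenced so the first entry stays 0.
        """
        perm = np.asarray(perm)
        logit = self.class_logit[perm]
        return ParameterSet(
            self.delta_beta[perm].copy(),
            self.item_discrimination.copy(),
            self.trait_scale[perm].copy(),
            logit - logit[0],
        )


@dataclass(frozen=True)
class QuadratureGrid:
    """Nodes and normalized weights approximating a standard-normal trait."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("quadrature nodes must be strictly increasing")
        if np.any(self.weights <= 0):
            raise ValueError("quadrature weights must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("quadrature weights must sum to 1")

    def __len__(self) -> int:
        return len(self.nodes)


def build_quadrature(n_points: int, kind: str = "gauss_hermite",
                     bound: float = 6.0) -> QuadratureGrid:
    """Build a quadrature grid for integrating over a standard-normal trait.

    ``gauss_hermite`` uses probabilists' Gauss-Hermite nodes with weights
    renormalized to sum to 1; ``rectangular`` uses an equispaced grid on
    ``[-bound, bound]`` with weights proportional to the normal density.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if kind == "gauss_hermite":
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_points)
    elif kind == "rectangular":
        nodes = np.linspace(-bound, bound, n_points)
        weights = norm.pdf(nodes)
    else:
        raise ValueError(f"unknown quadrature kind: {kind!r}")
    return QuadratureGrid(nodes, weights / weights.sum())


def class_proportions(class_logit) -> np.ndarray:
    """Softmax of the multinomial-logit class-size parameters."""
    class_logit = np.asarray(class_logit, dtype=float)
    if class_logit[0] != 0.0:
        raise ValueError("first class logit must be 0 (reference class)")
    return softmax(class_logit)


def _trait_sd(params: ParameterSet, trait_scale_is_variance: bool) -> np.ndarray:
    if trait_scale_is_variance:
        if np.any(params.trait_scale < 0):
            raise ValueError("trait variances must be non-negative")
        return np.sqrt(params.trait_scale)
    return params.trait_scale


def _log_prob_from_eta(eta: np.ndarray) -> np.ndarray:
    """Log category probabilities from cumulative step logits (last axis)."""
    return eta - logsumexp(eta, axis=-1, keepdims=True)


def log_prob_table(params: ParameterSet, nodes,
                   trait_scale_is_variance: bool = False) -> np.ndarray:
    """Log category probabilities on a trait grid.

    Returns an array of shape ``(G, Q, I, C)`` with
    ``table[g, q, i, c] = log P(X_i = c | class g, z = nodes[q])``.
    """
    nodes = np.atleast_1d(np.asarray(nodes, dtype=float))
    g_, i_, s_ = params.delta_beta.shape
    sd = _trait_sd(params, trait_scale_is_variance)
    trait = sd[:, None] * nodes[None, :]                       # (G, Q)
    step = (params.delta_beta[:, None, :, :]
            + params.item_discrimination[None, None, :, None]
            * trait[:, :, None, None])                         # (G, Q, I, S)
    eta = np.zeros((g_, nodes.size, i_, s_ + 1))
    np.cumsum(step, axis=-1, out=eta[..., 1:])
    return _log_prob_from_eta(eta)


def category_probabilities(params: ParameterSet, g: int, i: int, trait: float,
                           trait_scale_is_variance: bool = False) -> np.ndarray:
    """Category probability vector for one class, item and trait value.

    ``trait`` is the value of the standard-normal latent variable ``z``; the
    class scale multiplies it internally.
    """
    if not 0 <= g < params.n_classes:
        raise IndexError("class index out of range")
    if not 0 <= i < params.n_items:
        raise IndexError("item index out of range")
    if not np.isfinite(trait):
        raise ValueError("trait must be finite")
    table = log_prob_table(params, [trait], trait_scale_is_variance)
    return np.exp(table[g, 0, i])


def to_irt_parameters(params: ParameterSet):
    """Convert to the IRT (threshold) parameterization.

    Returns ``(tau, delta)`` with thresholds ``tau[g, i, s] =
    -delta_beta[g, i, s] / delta[i]`` and discriminations
    ``delta[i] = item_discrimination[i]``.
    """
    delta = params.item_discrimination
    if np.any(delta <= 0):
        raise ValueError("discriminations must be strictly positive")
    tau = -params.delta_beta / delta[None, :, None]
    return tau, delta.copy()


def from_irt_parameters(tau, delta, trait_scale, class_logit) -> ParameterSet:
    """Inverse of :func:`to_irt_parameters` (round-trip identity)."""
    tau = np.asarray(tau, dtype=float)
    delta = np.asarray(delta, dtype=float)
    return ParameterSet(-tau * delta[None, :, None], delta, trait_scale, class_logit)


def _check_responses(responses: np.ndarray, n_categories: int) -> np.ndarray:
    responses = np.asarray(responses)
    if responses.ndim != 2:
        raise ValueError("responses must be an N x I matrix")
    if responses.min() < 0 or responses.max() >= n_categories:
        raise ValueError("responses out of the coded category range")
    return responses.astype(np.intp)


def pattern_loglik(params: ParameterSet, responses, grid: QuadratureGrid,
                   trait_scale_is_variance: bool = False) -> np.ndarray:
    """Joint log "likelihood mass" per respondent, class and node.

    Returns ``(N, G, Q)`` with entries ``log(pi_g w_q P(pattern | g, node))``;
    marginal per-respondent likelihoods are logsumexp over the last two axes.
    """
    x = _check_responses(responses, params.n_categories)
    table = log_prob_table(params, grid.nodes, trait_scale_is_variance)
    table = np.clip(table, np.log(PROB_FLOOR), None)
    g_, q_, i_, _ = table.shape
    acc = np.zeros((x.shape[0], g_ * q_))
    flat = table.reshape(g_ * q_, i_, -1)
    for i in range(i_):
        acc += flat[:, i, :].T[x[:, i]]
    acc = acc.reshape(x.shape[0], g_, q_)
    log_pi = np.log(class_proportions(params.class_logit))
    return acc + log_pi[None, :, None] + np.log(grid.weights)[None, None, :]


def marginal_loglik(params: ParameterSet, responses, grid: QuadratureGrid,
                    trait_scale_is_variance: bool = False) -> float:
    """Marginal log-likelihood: trait integrated on the grid, classes summed."""
    joint = pattern_loglik(params, responses, grid, trait_scale_is_variance)
    return float(logsumexp(joint, axis=(1, 2)).sum())


# ---------------------------------------------------------------------------
# serialization

_PARAM_COLUMNS = ["model", "class", "item", "step", "parameter_type", "value"]


def parameter_table(params: ParameterSet, model: str = "") -> pd.DataFrame:
    """Flatten a :class:`ParameterSet` to a tidy table (bit-exact round-trip).

    Columns: model, class, item, step, parameter_type, value.  Class and item
    indices are 1-based in the table; fields that do not apply are 0.
    """
    rows = []
    g_, i_, s_ = params.delta_beta.shape
    for g in range(g_):
        for i in range(i_):
            for s in range(s_):
                rows.append((model, g + 1, i + 1, s + 1, "delta_beta",
                             params.delta_beta[g, i, s]))
    for i in range(i_):
        rows.append((model, 0, i + 1, 0, "item_discrimination",
                     params.item_discrimination[i]))
    for g in range(g_):
        rows.append((model, g + 1, 0, 0, "trait_scale", params.trait_scale[g]))
    for g in range(g_):
        rows.append((model, g + 1, 0, 0, "class_logit", params.class_logit[g]))
    return pd.DataFrame(rows, columns=_PARAM_COLUMNS)


def parameter_set_from_table(table: pd.DataFrame) -> ParameterSet:
    """Rebuild a :class:`ParameterSet` from :func:`parameter_table` output."""
    db = table[table.parameter_type == "delta_beta"]
    g_ = int(db["class"].max())
    i_ = int(db["item"].max())
    s_ = int(db["step"].max())
    delta = np.full((g_, i_, s_), np.nan)
    delta[db["class"] - 1, db["item"] - 1, db["step"] - 1] = db["value"].to_numpy()
    disc = np.empty(i_)
    dd = table[table.parameter_type == "item_discrimination"]
    disc[dd["item"].to_numpy() - 1] = dd["value"].to_numpy()
    scale = np.empty(g_)
    ts = table[table.parameter_type == "trait_scale"]
    scale[ts["class"].to_numpy() - 1] = ts["value"].to_numpy()
    logit = np.empty(g_)
    cl = table[table.parameter_type == "class_logit"]
    logit[cl["class"].to_numpy() - 1] = cl["value"].to_numpy()
    return ParameterSet(delta, disc, scale, logit)
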