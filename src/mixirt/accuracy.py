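"""Replication-wise accuracy battery for Monte Carlo parameter recovery.

Robust, median-based indices computed across replications against the
generating parameter values:

* ``RMdSE`` — root median squared error, ``sqrt(Md((p_hat - p)^2))``;
* ``bias_se`` — median absolute deviation of SE estimates from the
  empirical SD of the parameter estimates, ``Md(|se_hat - SD(p_hat)|)``;
* ``md_width_ci`` — median width of the 95% CI, ``Md(2 * z_.975 * se_hat)``;
* ``coverage`` — share of replications whose 95% CI contains the truth;
* Spearman rank concordance between generating and estimated adjacent-
  category (delta-beta) parameters, per item, averaged over items and
  replications.

Before the indices are computed, extreme parameter estimates (>|10|),
extreme standard errors (>50) and boundary-flagged standard errors are
excluded pairwise (the parameter and its SE together).  Per-coordinate
indices are aggregated within a parameter type and class by the median
(coverage by the mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .model import ParameterSet

__all__ = [
    "ReplicationStack",
    "AccuracySummary",
    "Z_975",
    "EXTREME_ESTIMATE",
    "EXTREME_SE",
    "stack_from_fits",
    "trim_estimates",
    "rmdse",
    "bias_se",
    "md_width_ci",
    "coverage",
    "spearman_concordance",
    "summarize_accuracy",
]

#: 97.5th standard-normal quantile, fixed for bit-stable CI widths
Z_975 = 1.959964
#: trimming cutoffs for parameter and standard-error estimates
EXTREME_ESTIMATE = 10.0
EXTREME_SE = 50.0

_TYPES = ("delta_beta", "item_discrimination", "trait_scale", "class_logit")


@dataclass
class ReplicationStack:
    """Label-aligned estimates and SEs across replications.

    Each block is an array with the replication axis first, e.g.
    ``delta_beta`` has shape (R, G, I, S).  ``exclude_*`` are boolean masks
    of the same shapes marking trimmed entries (estimate and SE pairwise).
    """

    delta_beta: np.ndarray
    item_discrimination: np.ndarray
    trait_scale: np.ndarray
    class_logit: np.ndarray
    se_delta_beta: np.ndarray
    se_item_discrimination: np.ndarray
    se_trait_scale: np.ndarray
    se_class_logit: np.ndarray
    exclude: dict = field(default_factory=dict)
    equal_discrimination: bool = False

    @property
    def n_replications(self) -> int:
        return self.delta_beta.shape[0]

    def estimates(self, ptype: str) -> np.ndarray:
        return getattr(self, ptype)

    def ses(self, ptype: str) -> np.ndarray:
        return getattr(self, "se_" + ptype)


def stack_from_fits(fits) -> ReplicationStack:
    """Build a stack from aligned fits (with SEs and boundary flags)."""
    if not fits:
        raise ValueError("need at least one fit")
    first = fits[0]

    def gather(attr, sub):
        return np.stack([getattr(getattr(f, attr), sub) for f in fits])

    stack = ReplicationStack(
        delta_beta=gather("params", "delta_beta"),
        item_discrimination=gather("params", "item_discrimination"),
        trait_scale=gather("params", "trait_scale"),
        class_logit=gather("params", "class_logit"),
        se_delta_beta=gather("standard_errors", "delta_beta"),
        se_item_discrimination=gather("standard_errors", "item_discrimination"),
        se_trait_scale=gather("standard_errors", "trait_scale"),
        se_class_logit=gather("standard_errors", "class_logit"),
        equal_discrimination=first.spec.equal_discrimination,
    )
    boundary = {t: gather("se_boundary", t).astype(bool) for t in _TYPES}
    return trim_estimates(stack, boundary)


def trim_estimates(stack: ReplicationStack,
                   boundary: dict | None = None) -> ReplicationStack:
    """Populate pairwise exclusion masks from the trimming rules.

    An entry is excluded when the estimate exceeds |10|, the SE exceeds 50,
    or the SE is boundary-flagged; the parameter and its SE are always
    dropped together.
    """
    for ptype in _TYPES:
        est = stack.estimates(ptype)
        se = stack.ses(ptype)
        with np.errstate(invalid="ignore"):
            mask = (np.abs(est) > EXTREME_ESTIMATE) | (se > EXTREME_SE)
        mask |= ~np.isfinite(est)
        if boundary is not None:
            mask |= boundary[ptype]
        stack.exclude[ptype] = mask
    return stack


def _kept(values: np.ndarray, excluded: np.ndarray | None) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if excluded is None:
        return values[np.isfinite(values)]
    return values[~np.asarray(excluded, dtype=bool) & np.isfinite(values)]


def rmdse(estimates, truth: float, excluded=None) -> float:
    """Root median squared error of one coordinate across replications."""
    vals = _kept(estimates, excluded)
    if vals.size == 0:
        return np.nan
    return float(np.sqrt(np.median((vals - truth) ** 2)))


def bias_se(se_estimates, empirical_sd: float, excluded=None) -> float:
    """Median absolute deviation of SE estimates from the empirical SD."""
    vals = _kept(se_estimates, excluded)
    if vals.size == 0 or not np.isfinite(empirical_sd):
        return np.nan
    return float(np.median(np.abs(vals - empirical_sd)))


def empirical_sd(estimates, excluded=None) -> float:
    """n-1 standard deviation of the non-excluded estimates."""
    vals = _kept(estimates, excluded)
    if vals.size < 2:
        return np.nan
    return float(np.std(vals, ddof=1))


def md_width_ci(se_estimates, excluded=None) -> float:
    """Median width of the 95% confidence interval across replications."""
    vals = _kept(se_estimates, excluded)
    if vals.size == 0:
        return np.nan
    return float(np.median(2.0 * Z_975 * vals))


def coverage(estimates, se_estimates, truth: float, excluded=None) -> float:
    """Share of replications whose 95% CI contains the generating value."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(se_estimates, dtype=float)
    keep = np.isfinite(est) & np.isfinite(se)
    if excluded is not None:
        keep &= ~np.asarray(excluded, dtype=bool)
    if keep.sum() == 0:
        return np.nan
    est, se = est[keep], se[keep]
    hit = (truth >= est - Z_975 * se) & (truth <= est + Z_975 * se)
    return float(hit.mean())


def spearman_concordance(stack: ReplicationStack, truth: ParameterSet,
                         use_exclusions: bool = True) -> np.ndarray:
    """Mean Spearman rank correlation per class.

    Per replication and item, the generating delta-betas are correlated with
    their estimates (average-rank tie handling, trimmed entries dropped
    pairwise); correlations are averaged over items, then over replications.
    """
    est = stack.delta_beta
    excl = stack.exclude.get("delta_beta")
    r_, g_, i_, _ = est.shape
    out = np.full(g_, np.nan)
    for g in range(g_):
        per_rep = []
        for r in range(r_):
            per_item = []
            for i in range(i_):
                x = truth.delta_beta[g, i]
                y = est[r, g, i]
                keep = np.isfinite(y)
                if use_exclusions and excl is not None:
                    keep &= ~excl[r, g, i]
                if keep.sum() >= 3:
                    per_item.append(
                        spearmanr(x[keep], y[keep]).statistic)
            if per_item:
                per_rep.append(np.mean(per_item))
        if per_rep:
            out[g] = float(np.mean(per_rep))
    return out


@dataclass
class AccuracySummary:
    """Tidy per (parameter type, class) accuracy table."""

    table: pd.DataFrame

    def value(self, ptype: str, index: str, klass: int | None = None) -> float:
        sub = self.table[(self.table.parameter_type == ptype)
                         & (self.table["index"] == index)]
        if klass is not None:
            sub = sub[sub["class"] == klass]
        if sub.empty:
            return np.nan
        return float(sub["value"].iloc[0])

    def max_over_classes(self, ptype: str, index: str) -> float:
        sub = self.table[(self.table.parameter_type == ptype)
                         & (self.table["index"] == index)]
        return float(sub["value"].max())


def _coord_iter(ptype: str, stack: ReplicationStack, truth: ParameterSet):
    """Yield (class_label, truth, estimates, ses, excluded) per coordinate.

    Class label 0 marks class-unspecific coordinates (discriminations).
    Reference-fixed coordinates (first discrimination, first class logit)
    are skipped; class-size accuracy is computed on the logit scale.
    """
    excl = stack.exclude.get(ptype)
    if ptype == "delta_beta":
        _, g_, i_, s_ = stack.delta_beta.shape
        for g in range(g_):
            for i in range(i_):
                for s in range(s_):
                    yield (g + 1, truth.delta_beta[g, i, s],
                           stack.delta_beta[:, g, i, s],
                           stack.se_delta_beta[:, g, i, s],
                           excl[:, g, i, s])
    elif ptype == "item_discrimination":
        for i in range(1, stack.item_discrimination.shape[1]):
            yield (0, truth.item_discrimination[i],
                   stack.item_discrimination[:, i],
                   stack.se_item_discrimination[:, i], excl[:, i])
    elif ptype == "trait_scale":
        for g in range(stack.trait_scale.shape[1]):
            yield (g + 1, truth.trait_scale[g], stack.trait_scale[:, g],
                   stack.se_trait_scale[:, g], excl[:, g])
    elif ptype == "class_logit":
        for g in range(1, stack.class_logit.shape[1]):
            yield (g + 1, truth.class_logit[g], stack.class_logit[:, g],
                   stack.se_class_logit[:, g], excl[:, g])


def summarize_accuracy(stack: ReplicationStack,
                       truth: ParameterSet) -> AccuracySummary:
    """Median-aggregated accuracy indices per parameter type and class."""
    types = list(_TYPES)
    if stack.equal_discrimination:
        types.remove("item_discrimination")
    rows = []
    for ptype in types:
        per_coord = {}
        for klass, tval, est, se, excl in _coord_iter(ptype, stack, truth):
            sd = empirical_sd(est, excl)
            rec = dict(
                rmdse=rmdse(est, tval, excl),
                bias_se=bias_se(se, sd, excl),
                md_width_ci=md_width_ci(se, excl),
                coverage=coverage(est, se, tval, excl),
                n_used=int((~excl).sum()),
                n_excluded=int(excl.sum()),
            )
            per_coord.setdefault(klass, []).append(rec)
        def _agg(values, func):
            values = np.asarray(values, dtype=float)
            values = values[np.isfinite(values)]
            return float(func(values)) if values.size else np.nan

        for klass, recs in sorted(per_coord.items()):
            frame = pd.DataFrame(recs)
            agg = {
                "rmdse": _agg(frame.rmdse, np.median),
                "bias_se": _agg(frame.bias_se, np.median),
                "md_width_ci": _agg(frame.md_width_ci, np.median),
                "coverage": _agg(frame.coverage, np.mean),
            }
            for index, value in agg.items():
                rows.append(dict(parameter_type=ptype, **{"class": klass},
                                 index=index, value=value,
                                 n_used=int(frame.n_used.sum()),
                                 n_excluded=int(frame.n_excluded.sum())))
    rs = spearman_concordance(stack, truth)
    for g, val in enumerate(rs, start=1):
        rows.append(dict(parameter_type="delta_beta", **{"class": g},
                         index="spearman", value=val,
                         n_used=stack.n_replications, n_excluded=0))
    return AccuracySummary(pd.DataFrame(rows))
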