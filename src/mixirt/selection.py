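"""Information criteria and latent-class enumeration.

Five penalized-likelihood criteria are compared for choosing the number of
latent classes::

    AIC   = -2 LL + 2 Npar
    BIC   = -2 LL + ln(N) Npar
    CAIC  = -2 LL + (ln(N) + 1) Npar
    AIC3  = -2 LL + 3 Npar
    SABIC = -2 LL + ln((N + 2) / 24) Npar

Natural logarithms throughout.  SABIC uses Sclove's sample-size-adjusted
penalty; a literal variant with ``ln(N + 224)`` is available for audit, but
that penalty is numerically indistinguishable from the BIC's and is not the
default.  The class solution with the smallest criterion value is selected;
ties break toward fewer classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelSpec

__all__ = [
    "CRITERIA",
    "SelectionTable",
    "count_free_parameters",
    "information_criteria",
    "select_best",
    "tabulate_selection",
]

CRITERIA = ("AIC", "BIC", "CAIC", "AIC3", "SABIC")

#: success threshold: a criterion is deemed reliable in a condition when it
#: recovers the true class count in at least this share of replications
SUCCESS_THRESHOLD = 95.0


def count_free_parameters(spec: ModelSpec) -> int:
    """Free parameters under the identification constraints.

    G*I*(C-1) adjacent-category parameters, I-1 discriminations (rmGPCM
    only), G-1 class logits and G trait scales.
    """
    g, i, c = spec.n_classes, spec.n_items, spec.n_categories
    n = g * i * (c - 1) + (g - 1) + g
    if not spec.equal_discrimination:
        n += i - 1
    return n


def information_criteria(loglik: float, n_par: int, n: int,
                         sabic_literal: bool = False) -> dict:
    """The five criteria for one fitted class solution."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    m2ll = -2.0 * loglik
    sabic_pen = math.log(n + 224.0) if sabic_literal else math.log((n + 2.0) / 24.0)
    return {
        "AIC": m2ll + 2.0 * n_par,
        "BIC": m2ll + math.log(n) * n_par,
        "CAIC": m2ll + (math.log(n) + 1.0) * n_par,
        "AIC3": m2ll + 3.0 * n_par,
        "SABIC": m2ll + sabic_pen * n_par,
    }


def select_best(criterion_values: dict, criterion: str | None = None) -> int:
    """Class count minimizing a criterion; ties break toward fewer classes.

    ``criterion_values`` maps class count -> criterion value (or, when
    ``criterion`` is given, class count -> dict of criterion values).
    Candidates with missing values (improper solutions excluded upstream)
    are skipped.
    """
    items = []
    for g, val in criterion_values.items():
        if criterion is not None:
            val = val[criterion]
        if val is not None and np.isfinite(val):
            items.append((int(g), float(val)))
    if not items:
        raise ValueError("no usable candidate class solution")
    items.sort(key=lambda t: t[0])
    best_g, best_v = items[0]
    for g, v in items[1:]:
        if v < best_v:
            best_g, best_v = g, v
    return best_g


@dataclass
class SelectionTable:
    """Selection percentages per criterion and candidate class count."""

    table: pd.DataFrame

    def percentage(self, criterion: str, n_classes: int) -> float:
        sub = self.table[self.table.criterion == criterion]
        col = f"pct_g{n_classes}"
        return float(sub[col].iloc[0]) if col in sub.columns else 0.0

    def success(self, criterion: str) -> bool:
        sub = self.table[self.table.criterion == criterion]
        return bool(sub["success"].iloc[0])


def tabulate_selection(records, true_classes: int,
                       candidates=None) -> SelectionTable:
    """Selection-rate table from per-replication selections.

    ``records`` is an iterable of dicts mapping criterion -> selected class
    count (replications whose true-class solution was improper are already
    dropped upstream and simply do not appear here).
    """
    records = list(records)
    if not records:
        raise ValueError("no replication records")
    if candidates is None:
        candidates = sorted({g for rec in records for g in rec.values()})
    rows = []
    for crit in CRITERIA:
        counts = {g: 0 for g in candidates}
        n_used = 0
        for rec in records:
            if crit not in rec:
                continue
            counts[rec[crit]] = counts.get(rec[crit], 0) + 1
            n_used += 1
        row = {"criterion": crit, "n_replications": n_used}
        for g in sorted(counts):
            row[f"pct_g{g}"] = 100.0 * counts[g] / n_used if n_used else np.nan
        pct_true = row.get(f"pct_g{true_classes}", 0.0)
        row["success"] = bool(n_used and pct_true >= SUCCESS_THRESHOLD)
        rows.append(row)
    return SelectionTable(pd.DataFrame(rows))
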