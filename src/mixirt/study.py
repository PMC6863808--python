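"""Condition orchestration: replications, label alignment, output tables.

One *condition* is a cell of the simulation design (model type, test
length, categories, latent mixture, sample size).  Per replication the
runner generates a dataset, fits every candidate class count (the true
count warm-started at the generating values, the others from random
starts), computes standard errors and posterior classification, applies
the improper-solution rule, aligns latent-class labels to the generating
model, and applies the five information criteria.  Conditions aggregate
into a convergence table, an accuracy summary, and a selection-rate table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .accuracy import AccuracySummary, stack_from_fits, summarize_accuracy
from .estimate import (
    FitConfig,
    FitResult,
    ParamBlocks,
    compute_standard_errors,
    diagnose_solution,
    fit_em,
    multi_start_fit,
    posterior_classification,
    refine_newton,
)
from .selection import (
    CRITERIA,
    SelectionTable,
    information_criteria,
    select_best,
    tabulate_selection,
)
from .simulate import (
    ConditionConfig,
    GeneratingFixture,
    derive_condition,
    generate_dataset,
    load_fixture,
    replication_seed,
)

__all__ = [
    "StudyConfig",
    "ReplicationRecord",
    "ConditionResult",
    "align_labels",
    "check_label_separation",
    "run_condition",
    "run_study",
    "export_tables",
    "study_from_yaml",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Scaled-down study settings.

    Defaults run 50 replications per condition with the true-class solution
    warm-started at the generating values plus 10 random start sets for
    every candidate class count; the full-scale setup (500 replications,
    100 start sets) is a matter of raising these numbers.
    """

    conditions: list = field(default_factory=list)
    fit: FitConfig = field(default_factory=FitConfig)
    base_seed: int = 0
    n_random_starts: int = 10
    start_em_iter: int = 200
    warm_start_true: bool = True
    refine: bool = False
    compute_se: bool = True
    candidates: tuple | None = None
    n_workers: int = 1

    def candidate_set(self, condition: ConditionConfig) -> tuple:
        if self.candidates is not None:
            cands = tuple(self.candidates)
        else:
            g = condition.true_classes
            cands = tuple(k for k in (g - 1, g, g + 1) if k >= 1)
        if condition.true_classes not in cands:
            raise ValueError("candidate set must include the true class count")
        return cands


@dataclass
class ReplicationRecord:
    """Everything retained from one replication."""

    condition_id: str
    replication: int
    seed: int
    candidate_summaries: dict            # G -> dict of scalars
    selected: dict                       # criterion -> class count (or None)
    aligned_fit: FitResult | None        # true-G fit, labels aligned
    permutation: tuple | None
    true_improper: bool


@dataclass
class ConditionResult:
    condition: ConditionConfig
    records: list
    accuracy: AccuracySummary | None
    selection: SelectionTable | None
    convergence: pd.DataFrame


# ---------------------------------------------------------------------------
# label alignment

def _permute_blocks(blocks: ParamBlocks, perm) -> ParamBlocks:
    out = blocks.copy()
    out.delta_beta = out.delta_beta[list(perm)]
    out.trait_scale = out.trait_scale[list(perm)]
    out.class_logit = out.class_logit[list(perm)]
    return out


def align_labels(fit: FitResult, truth: ParameterSet):
    """Resolve label switching against the generating model.

    Exhaustively searches class permutations for the one minimizing the sum
    of squared differences between generating and estimated delta-beta
    vectors, and applies it to every class-indexed block (class logits are
    re-referenced to keep the first entry at 0; their standard errors are
    permuted as-is and are exact only for the identity permutation).
    """
    g = truth.n_classes
    if fit.spec.n_classes != g:
        raise ValueError("fit and truth must share the number of classes")
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(g)):
        cost = float(np.sum((fit.params.delta_beta[list(perm)]
                             - truth.delta_beta) ** 2))
        if cost < best_cost:
            best_perm, best_cost = perm, cost
    if best_perm == tuple(range(g)):
        return best_perm, fit
    aligned = FitResult(**{**fit.__dict__})
    aligned.params = fit.params.permute_classes(list(best_perm))
    for attr in ("standard_errors", "se_boundary", "param_boundary"):
        blocks = getattr(fit, attr)
        if blocks is not None:
            setattr(aligned, attr, _permute_blocks(blocks, best_perm))
    if fit.posterior is not None:
        aligned.posterior = fit.posterior[:, list(best_perm)]
    return best_perm, aligned


def check_label_separation(stack, random_state: int = 0) -> dict:
    """Certify the absence of label switching across replications.

    Fits a multinomial logistic classifier on the per-(replication, class)
    delta-beta vectors with the class identity as the label; error-free
    training classification ("complete separation") certifies that class
    labels are consistently ordered across replications.
    """
    from sklearn.linear_model import LogisticRegression

    delta = np.asarray(stack.delta_beta if hasattr(stack, "delta_beta")
                       else stack)
    if delta.ndim != 4:
        raise ValueError("expected a (R, G, I, S) delta-beta stack")
    r_, g_, i_, s_ = delta.shape
    if r_ < 2:
        raise ValueError("need at least 2 replications")
    if g_ < 2:
        raise ValueError("separation is undefined for a single class")
    x = delta.reshape(r_ * g_, i_ * s_)
    y = np.tile(np.arange(g_), r_)
    # moderate regularization: with tight, widely separated class clusters
    # the training classification stays error-free, while an unregularized
    # fit could linearly separate even a mislabeled replication in the
    # high-dimensional feature space and mask the violation
    clf = LogisticRegression(C=1.0, max_iter=2000, random_state=random_state)
    clf.fit(x, y)
    pred = clf.predict(x)
    n_err = int((pred != y).sum())
    return {"separated": n_err == 0, "n_misclassified": n_err,
            "n_vectors": int(r_ * g_)}


# ---------------------------------------------------------------------------
# replication and condition drivers

def _fit_candidate(responses, spec, truth, study: StudyConfig, seed: int,
                   is_true_g: bool) -> FitResult:
    cfg = replace(study.fit,
                  n_starts=max(study.n_random_starts, 1),
                  start_em_iter=study.start_em_iter,
                  warm_start=truth if (is_true_g and study.warm_start_true)
                  else None)
    if study.n_random_starts == 0 and cfg.warm_start is not None:
        fit = fit_em(responses, spec, cfg.warm_start, cfg)
        if study.refine:
            fit = refine_newton(fit, responses, cfg)
        return fit
    fit = multi_start_fit(responses, spec, cfg, seed=seed)
    if not study.refine:
        # multi_start_fit always refines; refit from the best start instead
        fit = fit_em(responses, spec, fit.params, cfg)
    return fit


def run_replication(condition: ConditionConfig, study: StudyConfig,
                    fixture: GeneratingFixture, rep: int) -> ReplicationRecord:
    truth = derive_condition(fixture, condition)
    seed = replication_seed(study.base_seed, condition.condition_id, rep)
    data = generate_dataset(truth, condition.sample_size, seed, condition)
    cfg = replace(study.fit)
    summaries = {}
    fits = {}
    for g in study.candidate_set(condition):
        spec = condition.model_spec(n_classes=g)
        try:
            fit = _fit_candidate(data.responses, spec, truth, study,
                                 seed + g, g == condition.true_classes)
        except (FloatingPointError, RuntimeError) as exc:
            logger.warning("%s rep %d G=%d failed: %s",
                           condition.condition_id, rep, g, exc)
            summaries[g] = {"failed": True}
            continue
        if study.compute_se:
            fit = compute_standard_errors(fit, data.responses, cfg)
            diagnose_solution(fit)
        fit = posterior_classification(fit, data.responses, cfg)
        ics = information_criteria(fit.loglik, fit.n_free_parameters,
                                   condition.sample_size)
        summaries[g] = {
            "failed": False, "loglik": fit.loglik,
            "n_par": fit.n_free_parameters,
            "em_converged": fit.em_converged,
            "em_iterations": fit.em_iterations,
            "nr_converged": fit.nr_converged,
            "nr_iterations": fit.nr_iterations,
            "improper": fit.improper,
            "mean_assignment_probability": fit.mean_assignment_probability,
            **ics,
        }
        fits[g] = fit
    true_g = condition.true_classes
    true_improper = summaries.get(true_g, {}).get("improper", True) or \
        summaries.get(true_g, {}).get("failed", True)
    selected = {}
    if not true_improper:
        # improper non-true candidates are excluded from each argmin
        usable = {g: s for g, s in summaries.items()
                  if not s.get("failed") and not s.get("improper")}
        for crit in CRITERIA:
            try:
                selected[crit] = select_best(
                    {g: s[crit] for g, s in usable.items()})
            except ValueError:
                pass
    perm, aligned = (None, None)
    if true_g in fits and not true_improper:
        perm, aligned = align_labels(fits[true_g], truth)
    return ReplicationRecord(
        condition_id=condition.condition_id, replication=rep, seed=seed,
        candidate_summaries=summaries, selected=selected,
        aligned_fit=aligned, permutation=perm, true_improper=true_improper,
    )


def _convergence_row(condition: ConditionConfig, records) -> dict:
    g = condition.true_classes
    rows = [r.candidate_summaries.get(g, {}) for r in records]
    ok = [r for r in rows if r and not r.get("failed")]
    em_iters = [r["em_iterations"] for r in ok]
    n_improper = sum(bool(r.get("improper")) for r in ok)
    return {
        "condition": condition.condition_id,
        "model": condition.model_type,
        "N": condition.sample_size,
        "n_replications": len(records),
        "conv_em_pct": 100.0 * np.mean([r["em_converged"] for r in ok])
        if ok else np.nan,
        "md_em_iter": float(np.median(em_iters)) if em_iters else np.nan,
        "min_em_iter": int(np.min(em_iters)) if em_iters else 0,
        "max_em_iter": int(np.max(em_iters)) if em_iters else 0,
        "conv_nr_pct": 100.0 * np.mean([r["nr_converged"] for r in ok])
        if ok else np.nan,
        "n_improper": n_improper,
        "mean_assignment_probability": float(np.mean(
            [r["mean_assignment_probability"] for r in ok])) if ok else np.nan,
    }


def run_condition(condition: ConditionConfig, study: StudyConfig,
                  fixture: GeneratingFixture | None = None) -> ConditionResult:
    """All replications of one condition plus the summary tables.

    Individual replication failures are recorded, never fatal.  Fully
    reproducible from ``study.base_seed``; replications are independent
    work units keyed by their own seeds, so results do not depend on
    scheduling order.
    """
    fixture = fixture or load_fixture()
    reps = range(condition.n_replications)
    if study.n_workers > 1:
        from joblib import Parallel, delayed
        records = Parallel(n_jobs=study.n_workers)(
            delayed(run_replication)(condition, study, fixture, r)
            for r in reps)
    else:
        records = [run_replication(condition, study, fixture, r)
                   for r in reps]
    truth = derive_condition(fixture, condition)
    proper = [r.aligned_fit for r in records if r.aligned_fit is not None
              and r.aligned_fit.standard_errors is not None]
    accuracy = None
    if proper:
        stack = stack_from_fits(proper)
        accuracy = summarize_accuracy(stack, truth)
    selection = None
    sel_records = [r.selected for r in records if r.selected]
    if sel_records:
        selection = tabulate_selection(
            sel_records, condition.true_classes,
            candidates=list(study.candidate_set(condition)))
    convergence = pd.DataFrame([_convergence_row(condition, records)])
    return ConditionResult(condition, records, accuracy, selection,
                           convergence)


def run_study(study: StudyConfig) -> list:
    return [run_condition(c, study) for c in study.conditions]


# ---------------------------------------------------------------------------
# export

def export_tables(results, out_dir) -> dict:
    """Write the summary tables of one or more conditions as tidy CSVs.

    Emits ``convergence.csv``, ``accuracy.csv``, ``selection.csv``, a
    combined long-format ``selection_long.csv`` (one row per condition x
    criterion x candidate) and per-replication ``records.csv``.  Numbers
    are rounded only at export (selection percentages to integers).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(results, (list, tuple)):
        results = [results]
    if not results:
        raise ValueError("no condition results to export")

    conv = pd.concat([r.convergence for r in results], ignore_index=True)
    conv.to_csv(out / "convergence.csv", index=False)

    acc_frames = []
    for r in results:
        if r.accuracy is not None:
            t = r.accuracy.table.copy()
            t.insert(0, "condition", r.condition.condition_id)
            t.insert(1, "N", r.condition.sample_size)
            t.insert(2, "model", r.condition.model_type)
            acc_frames.append(t)
    if acc_frames:
        pd.concat(acc_frames, ignore_index=True).to_csv(
            out / "accuracy.csv", index=False)

    sel_frames, long_rows = [], []
    for r in results:
        if r.selection is None:
            continue
        t = r.selection.table.copy()
        for col in t.columns:
            if col.startswith("pct_g"):
                t[col] = t[col].fillna(0.0).round(0).astype(int)
        t.insert(0, "condition", r.condition.condition_id)
        t.insert(1, "N", r.condition.sample_size)
        sel_frames.append(t)
        for _, row in r.selection.table.iterrows():
            for col in r.selection.table.columns:
                if col.startswith("pct_g"):
                    long_rows.append({
                        "condition": r.condition.condition_id,
                        "N": r.condition.sample_size,
                        "criterion": row["criterion"],
                        "n_classes": int(col[5:]),
                        "pct": 0.0 if pd.isna(row[col]) else row[col],
                    })
    if sel_frames:
        pd.concat(sel_frames, ignore_index=True).to_csv(
            out / "selection.csv", index=False)
        pd.DataFrame(long_rows).to_csv(out / "selection_long.csv",
                                       index=False)

    rec_rows = []
    for r in results:
        for rec in r.records:
            base = {"condition": rec.condition_id,
                    "replication": rec.replication, "seed": rec.seed,
                    "true_improper": rec.true_improper}
            for g, s in rec.candidate_summaries.items():
                row = dict(base)
                row["n_classes"] = g
                row.update({k: v for k, v in s.items()})
                for crit, sel in rec.selected.items():
                    row[f"selected_{crit}"] = sel
                rec_rows.append(row)
    pd.DataFrame(rec_rows).to_csv(out / "records.csv", index=False)
    return {"out_dir": str(out)}


def study_from_yaml(path) -> StudyConfig:
    """Build a :class:`StudyConfig` from a YAML file.

    Top-level keys mirror the dataclass fields; ``conditions`` is a list of
    mappings with :class:`~mixirt.simulate.ConditionConfig` fields; ``fit``
    holds :class:`~mixirt.estimate.FitConfig` overrides.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    conditions = [ConditionConfig(**c) for c in raw.pop("conditions", [])]
    fit = FitConfig(**raw.pop("fit", {}))
    cands = raw.pop("candidates", None)
    return StudyConfig(conditions=conditions, fit=fit,
                       candidates=tuple(cands) if cands else None, **raw)
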