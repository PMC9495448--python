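"""Heterogeneous ensemble integrators over the base prediction matrix.

Three integrator families combine the local models' out-of-fold scores:

* **mean aggregation** — the unweighted mean of all base prediction columns;
* **CES** — Caruana-style iterative ensemble selection with replacement:
  starting from the empty set, greedily add the column whose inclusion most
  improves the ensemble's performance on the outer-training base
  predictions, stopping when no strict gain remains;
* **stacking** — a second-level (meta) classifier trained on the base
  predictions as features.

A default run fits one mean, one CES and nine stacking models (one per
meta-algorithm), i.e. eleven ensemble variants, and evaluates each on the
pooled outer-test scores.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import (BasePredictionMatrix, ColumnId, FoldPlan,
                         MultimodalDataset, RunConfig, column_label,
                         write_fold_plan, write_predictions)
from .evaluation import EvaluationReport, auprc, evaluate_scores, fmax
from .local_layer import (BaseClassifierSpec, LocalModelCollection,
                          generate_base_predictions, make_fold_plan,
                          normalize_roster, score_estimator,
                          train_local_models)

logger = logging.getLogger("ensint")

MetricFn = Callable[[np.ndarray, np.ndarray], float]

METRICS: dict[str, MetricFn] = {
    "fmax": lambda y, s: fmax(y, s)[0],
    "auprc": auprc,
}


# ---------------------------------------------------------------------------
# Ensemble model container
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """A fitted integrator over a fixed universe of base-prediction columns."""

    variant: str  # "mean" | "ces" | "stacking"
    column_ids: list[ColumnId]
    selection: Counter = field(default_factory=Counter)  # ces multiset
    trajectory: list[tuple[ColumnId, float]] = field(default_factory=list)
    meta_spec: BaseClassifierSpec | None = None
    meta_estimator: Any = None
    failed: bool = False
    failure: str = ""

    @property
    def model_id(self) -> str:
        if self.variant == "stacking":
            return f"stacking:{self.meta_spec.algorithm}"
        return self.variant

    def predict(self, bpm: BasePredictionMatrix) -> np.ndarray:
        if self.variant == "mean":
            return mean_aggregate(bpm)
        if self.variant == "ces":
            return ces_predict(self, bpm)
        if self.failed or self.meta_estimator is None:
            raise RuntimeError(f"stacking model {self.model_id} is not usable")
        X = _column_matrix(bpm, self.column_ids)
        return score_estimator(self.meta_estimator, X)


def _column_matrix(bpm: BasePredictionMatrix,
                   columns: Sequence[ColumnId]) -> np.ndarray:
    missing = [c for c in columns if c not in bpm.column_ids]
    if missing:
        raise ValueError(f"prediction matrix lacks column(s): {missing}")
    idx = [bpm.column_ids.index(c) for c in columns]
    return bpm.scores[:, idx]


# ---------------------------------------------------------------------------
# Mean aggregation
# ---------------------------------------------------------------------------

def mean_aggregate(bpm: BasePredictionMatrix) -> np.ndarray:
    """Per-entity arithmetic mean of the base prediction columns."""
    if bpm.n_columns == 0:
        raise ValueError("cannot aggregate an empty prediction matrix")
    return bpm.scores.mean(axis=1)


# ---------------------------------------------------------------------------
# CES: iterative ensemble selection with replacement
# ---------------------------------------------------------------------------

def ces_fit(train_bpm: BasePredictionMatrix, labels: np.ndarray,
            metric: str | MetricFn = "fmax", max_iterations: int = 100,
            seed: int = 0) -> EnsembleModel:
    """Greedy forward ensemble selection with replacement.

    At each step, for every column, evaluate the metric of the mean of the
    current multiset plus that column on the training base predictions; add
    the argmax if it strictly improves the current value (ties broken toward
    the lowest column index), otherwise stop. ``seed`` is accepted for API
    symmetry; the procedure is deterministic.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if train_bpm.n_columns == 0:
        raise ValueError("empty prediction matrix")
    metric_fn = METRICS[metric] if isinstance(metric, str) else metric
    y = np.asarray(labels, dtype=int)
    S = train_bpm.scores
    model = EnsembleModel("ces", list(train_bpm.column_ids))
    total = np.zeros(S.shape[0])
    count = 0
    best = -np.inf
    for _ in range(max_iterations):
        cand = (total[:, None] + S) / (count + 1)
        vals = np.array([metric_fn(y, cand[:, j]) for j in range(S.shape[1])])
        j = int(np.argmax(vals))  # first max -> lowest column index on ties
        if vals[j] <= best:
            break
        best = float(vals[j])
        total += S[:, j]
        count += 1
        col = train_bpm.column_ids[j]
        model.selection[col] += 1
        model.trajectory.append((col, best))
    return model


def ces_predict(model: EnsembleModel, bpm: BasePredictionMatrix) -> np.ndarray:
    """Multiplicity-weighted mean of the selected columns."""
    if not model.selection:
        raise ValueError("CES model has an empty selection multiset")
    cols = sorted(model.selection)
    weights = np.array([model.selection[c] for c in cols], dtype=float)
    X = _column_matrix(bpm, cols)
    return X @ (weights / weights.sum())


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

def stacking_fit(train_bpm: BasePredictionMatrix, labels: np.ndarray,
                 meta_spec: str | BaseClassifierSpec, seed: int = 0,
                 ) -> EnsembleModel:
    """Fit a second-level (meta) classifier on the base predictions.

    The training matrix is expected to satisfy the out-of-fold contract
    (scores produced by models that never saw the scored entity); a matrix
    without provenance records is accepted with a warning.
    """
    if not isinstance(meta_spec, BaseClassifierSpec):
        meta_spec = BaseClassifierSpec.from_entry(meta_spec)
    if not train_bpm.provenance:
        logger.warning("stacking on a prediction matrix without provenance; "
                       "out-of-fold contract not verifiable")
    model = EnsembleModel("stacking", list(train_bpm.column_ids),
                          meta_spec=meta_spec)
    try:
        est = meta_spec.build(seed)
        est.fit(train_bpm.scores, np.asarray(labels, dtype=int))
        model.meta_estimator = est
    except Exception as exc:  # noqa: BLE001 — contract: record failure
        model.failed = True
        model.failure = f"{type(exc).__name__}: {exc}"
        logger.warning("stacking meta %s failed: %s", meta_spec.algorithm,
                       model.failure)
    return model


# ---------------------------------------------------------------------------
# Top-level driver
# ---------------------------------------------------------------------------

@dataclass
class EIResult:
    """Artifacts of one EI run: fold plan, local models, base predictions,
    fitted ensembles per outer fold, pooled outer-test scores and reports."""

    config: RunConfig
    plan: FoldPlan
    labels: Any  # LabelVector
    models: LocalModelCollection
    train_bpms: dict[int, BasePredictionMatrix]
    test_bpms: dict[int, BasePredictionMatrix]
    ensembles: dict[tuple[str, int], EnsembleModel]
    pooled_scores: dict[str, pd.Series]
    reports: dict[str, EvaluationReport]
    fold_reports: dict[tuple[str, int], EvaluationReport]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.pooled_scores)

    def best_variant(self, measure: str = "fmax") -> str:
        return max(self.reports, key=lambda v: getattr(self.reports[v], measure))

    def report_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({v: r.as_dict() for v, r in self.reports.items()}).T
        df.index.name = "model_id"
        return df


def run_ei(dataset: MultimodalDataset, config: RunConfig,
           out_dir: str | Path | None = None) -> EIResult:
    """Execute the full EI pipeline under nested cross-validation.

    Trains the local-model grid, builds out-of-fold base prediction
    matrices, fits every ensemble variant (mean, CES, one stacking model per
    meta-algorithm) on each outer-training matrix, scores the outer-test
    entities, and evaluates each variant on the scores pooled across outer
    folds (per-fold reports are also kept). With the default rosters this
    yields eleven ensemble variants.
    """
    labels = dataset.labels
    plan = make_fold_plan(labels, config.k_outer, config.k_inner, config.seed)
    local_roster = normalize_roster(config.local_roster)
    meta_roster = normalize_roster(config.meta_roster)
    models = train_local_models(dataset, plan, local_roster,
                                undersample=config.undersample,
                                seed=config.seed)
    train_bpms, test_bpms = generate_base_predictions(models, dataset, plan)

    variants: list[tuple[str, Callable[[BasePredictionMatrix, np.ndarray, int],
                                       EnsembleModel]]] = []
    variants.append(("mean", lambda bpm, y, s: EnsembleModel(
        "mean", list(bpm.column_ids))))
    variants.append(("ces", lambda bpm, y, s: ces_fit(
        bpm, y, config.ces_metric, config.ces_max_iterations, s)))
    for spec in meta_roster:
        variants.append((f"stacking:{spec.algorithm}",
                         lambda bpm, y, s, spec=spec: stacking_fit(bpm, y, spec, s)))

    label_series = labels.as_series()
    ensembles: dict[tuple[str, int], EnsembleModel] = {}
    pooled_scores: dict[str, pd.Series] = {}
    reports: dict[str, EvaluationReport] = {}
    fold_reports: dict[tuple[str, int], EvaluationReport] = {}
    for variant_id, fit in variants:
        frames = []
        ok = True
        for o in range(plan.k_outer):
            y_train = label_series.loc[train_bpms[o].entity_ids].to_numpy()
            ens = fit(train_bpms[o], y_train,
                      config.derive_seed("ensemble", variant_id, o))
            ensembles[(variant_id, o)] = ens
            if ens.failed:
                ok = False
                continue
            scores = ens.predict(test_bpms[o])
            frames.append(pd.Series(scores, index=test_bpms[o].entity_ids))
            y_test = label_series.loc[test_bpms[o].entity_ids].to_numpy()
            try:
                fold_reports[(variant_id, o)] = evaluate_scores(y_test, scores)
            except ValueError:
                pass  # degenerate fold (single class); pooled report still valid
        if not ok:
            logger.warning("variant %s failed in at least one fold; skipped",
                           variant_id)
            continue
        pooled = pd.concat(frames).loc[labels.entity_ids]
        pooled_scores[variant_id] = pooled
        reports[variant_id] = evaluate_scores(labels.labels, pooled.to_numpy())

    result = EIResult(config, plan, labels, models, train_bpms, test_bpms,
                      ensembles, pooled_scores, reports, fold_reports)
    if out_dir is not None:
        write_ei_artifacts(result, Path(out_dir))
    return result


def write_ei_artifacts(result: EIResult, out_dir: Path) -> None:
    """Write the fold plan, per-fold prediction matrices, pooled per-model
    outer-test predictions and the evaluation report to ``out_dir``."""
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fold_plan(result.plan, out_dir / "fold_plan.tsv")
    for o, bpm in result.train_bpms.items():
        write_predictions(bpm, out_dir / f"base_predictions_train_fold{o}.tsv")
    for o, bpm in result.test_bpms.items():
        write_predictions(bpm, out_dir / f"base_predictions_test_fold{o}.tsv")
    label_series = result.labels.as_series()
    rows = []
    for variant_id, pooled in result.pooled_scores.items():
        for e, s in pooled.items():
            rows.append({"entity_id": e,
                         "outer_fold": result.plan.outer_assignment[e],
                         "model_id": variant_id, "score": s,
                         "label": int(label_series[e])})
    pred = pd.DataFrame(rows)
    pred.to_csv(out_dir / "ensemble_predictions.tsv", sep="\t", index=False,
                float_format="%.17g")
    result.report_frame().to_csv(out_dir / "report.tsv", sep="\t",
                                 float_format="%.17g")
    (out_dir / "report.json").write_text(json.dumps(
        {v: r.as_dict() for v, r in result.reports.items()}, indent=1))
    manifest = {
        "n_variants": len(result.pooled_scores),
        "variants": list(result.pooled_scores),
        "failed_variants": sorted({v for (v, _), e in result.ensembles.items()
                                   if e.failed}),
        "dropped_columns": [],
        "seed": result.config.seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
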