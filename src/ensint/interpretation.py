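"""Rank-product interpretation of EI models.

Feature importance is assembled from two ingredients, each expressed as a
percentile rank in (0, 1] where smaller = more important:

* **local feature ranks (LFRs)** — within each local model, the drop in
  cross-validated performance (AUPRC by default) when a feature is held out
  of training, ranked across the modality's features;
* **local model ranks (LMRs)** — within an ensemble, the contribution of
  each local model: uniform for mean aggregation, selection-multiset
  inclusion counts for CES, and permutation importance of the model's score
  column for stacking.

The rank product score of a feature is the mean, over the local models
whose modality contains it, of LMR x LFR; features are reported in
ascending RPS order (smallest = most important overall).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.inspection import permutation_importance
from sklearn.metrics import make_scorer
from sklearn.model_selection import StratifiedKFold

from .data_model import (BasePredictionMatrix, ColumnId, LabelVector,
                         ModalityTable, MultimodalDataset, RunConfig,
                         derive_seed)
from .ensemble_layer import EnsembleModel, ces_fit, stacking_fit
from .evaluation import auprc
from .local_layer import (BaseClassifierSpec, LocalModel, normalize_roster,
                          score_estimator)
from .preprocessing import undersample_majority

logger = logging.getLogger("ensint")


# ---------------------------------------------------------------------------
# Percentile ranks
# ---------------------------------------------------------------------------

def to_percentile_ranks(scores: Mapping[str, float] | Mapping[ColumnId, float],
                        higher_is_better: bool = True) -> dict:
    """Normalize importance values to percentile ranks in (0, 1].

    The most important item gets 1/n and the least important 1; ties take
    the mean of the ranks they occupy, divided by n.
    """
    keys = list(scores)
    if not keys:
        raise ValueError("empty score mapping")
    vals = np.array([float(scores[k]) for k in keys])
    if np.isnan(vals).any():
        raise ValueError("NaN importance value")
    ranked = rankdata(-vals if higher_is_better else vals, method="average")
    n = len(keys)
    return {k: float(r) / n for k, r in zip(keys, ranked)}


# ---------------------------------------------------------------------------
# Local feature ranks
# ---------------------------------------------------------------------------

@dataclass
class LocalFeatureRanks:
    """Percentile feature ranks of one local model (its modality's features)."""

    model_column: ColumnId
    modality: str
    ranks: dict[str, float]


def _cv_metric(spec: BaseClassifierSpec, X: np.ndarray, y: np.ndarray,
               cv_folds: int, seed: int) -> float:
    """AUPRC of out-of-fold scores under stratified k-fold CV."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    k = max(2, min(cv_folds, n_pos, n_neg))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        est = spec.build(derive_seed(seed, "lfr-cv", fold))
        est.fit(X[tr], y[tr])
        oof[te] = score_estimator(est, X[te])
    return auprc(y, oof)


def compute_lfr(model: LocalModel, train_table: ModalityTable,
                labels: LabelVector, metric: str = "auprc",
                cv_folds: int = 5, seed: int = 0) -> LocalFeatureRanks:
    """Held-out-feature importance of every feature of a local model.

    Importance of feature f = CV metric of the model retrained with all
    features minus the CV metric of the model retrained without f, both
    evaluated by stratified cross-validation on the model's own training
    entities. Importances are converted to percentile ranks (higher
    importance -> smaller rank). A single-feature modality trivially gets
    rank 1.0 for its feature.
    """
    if metric != "auprc":
        raise ValueError("only the AUPRC local-rank metric is implemented")
    features = model.feature_names
    if len(features) == 1:
        return LocalFeatureRanks(model.column, model.modality, {features[0]: 1.0})
    eidx = train_table.entity_index()
    rows = [eidx[e] for e in model.train_entities]
    X = train_table.values[rows]
    y = labels.subset(model.train_entities).labels
    base_seed = derive_seed(seed, "lfr", model.modality, model.spec.algorithm)
    full = _cv_metric(model.spec, X, y, cv_folds, base_seed)
    importances = {}
    for j, f in enumerate(features):
        X_wo = np.delete(X, j, axis=1)
        importances[f] = full - _cv_metric(model.spec, X_wo, y, cv_folds, base_seed)
    return LocalFeatureRanks(model.column, model.modality,
                             to_percentile_ranks(importances, higher_is_better=True))


# ---------------------------------------------------------------------------
# Local model ranks
# ---------------------------------------------------------------------------

@dataclass
class LocalModelRanks:
    """Percentile ranks of the local-model columns within one ensemble."""

    ensemble_id: str
    ranks: dict[ColumnId, float]


def compute_lmr(ensemble: EnsembleModel, train_bpm: BasePredictionMatrix,
                labels: np.ndarray, n_permutations: int = 100,
                seed: int = 0) -> LocalModelRanks:
    """Rank every base-prediction column by its contribution to an ensemble.

    * mean aggregation: every column contributes identically; all columns
      receive the average percentile (n+1)/(2n), which keeps the RPS scale
      comparable across variants without affecting within-ensemble ordering.
    * CES: importance = number of inclusions in the selection multiset
      (columns never selected tie at the worst rank).
    * stacking: importance = mean AUPRC drop over ``n_permutations`` random
      permutations of the column's scores, with the fitted meta-model
      re-scored (not retrained); deterministic under ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    cols = list(ensemble.column_ids)
    n = len(cols)
    if ensemble.variant == "mean":
        ranks = {c: (n + 1) / (2 * n) for c in cols}
    elif ensemble.variant == "ces":
        counts = {c: float(ensemble.selection.get(c, 0)) for c in cols}
        ranks = to_percentile_ranks(counts, higher_is_better=True)
    elif ensemble.variant == "stacking":
        if ensemble.failed or ensemble.meta_estimator is None:
            raise ValueError("cannot rank columns of a failed stacking model")
        X = np.column_stack([train_bpm.column(c) for c in cols])
        y = np.asarray(labels, dtype=int)
        scorer = make_scorer(auprc, response_method=("predict_proba",
                                                     "decision_function"))
        result = permutation_importance(
            ensemble.meta_estimator, X, y, scoring=scorer,
            n_repeats=n_permutations, random_state=seed % (2**31))
        ranks = to_percentile_ranks(
            {c: float(v) for c, v in zip(cols, result.importances_mean)},
            higher_is_better=True)
    else:
        raise ValueError(f"unknown ensemble variant {ensemble.variant!r}")
    return LocalModelRanks(ensemble.model_id, ranks)


# ---------------------------------------------------------------------------
# Rank product scores
# ---------------------------------------------------------------------------

def rank_product_scores(lmr: LocalModelRanks,
                        lfrs: Sequence[LocalFeatureRanks]) -> pd.DataFrame:
    """Combine LMRs and LFRs into per-feature rank product scores.

    RPS(f) = mean over local models m whose modality contains f of
    LMR(m) x LFR(f | m). Feature names must be unique across modalities
    (modality-qualify them upstream if they are not). Returns a DataFrame
    (``modality``, ``feature``, ``rps``) sorted ascending by RPS.
    """
    feature_modality: dict[str, str] = {}
    for lfr in lfrs:
        if lfr.model_column not in lmr.ranks:
            raise ValueError(f"no LMR for local model {lfr.model_column}")
        for f in lfr.ranks:
            prev = feature_modality.get(f)
            if prev is not None and prev != lfr.modality:
                raise ValueError(
                    f"feature {f!r} appears in modalities {prev!r} and "
                    f"{lfr.modality!r}; feature names must be modality-qualified")
            feature_modality[f] = lfr.modality
    products: dict[str, list[float]] = {f: [] for f in feature_modality}
    for lfr in lfrs:
        w = lmr.ranks[lfr.model_column]
        for f, r in lfr.ranks.items():
            products[f].append(w * r)
    rows = [{"modality": feature_modality[f], "feature": f,
             "rps": float(np.mean(p))} for f, p in products.items()]
    df = pd.DataFrame(rows, columns=["modality", "feature", "rps"])
    return df.sort_values(["rps", "modality", "feature"],
                          kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Whole-dataset interpretation driver
# ---------------------------------------------------------------------------

@dataclass
class InterpretationResult:
    """RPS table plus the intermediate ranks it was assembled from."""

    rps: pd.DataFrame
    lmr: LocalModelRanks
    lfrs: list[LocalFeatureRanks]
    ensemble: EnsembleModel


def full_data_base_predictions(dataset: MultimodalDataset, config: RunConfig,
                               ) -> tuple[BasePredictionMatrix,
                                          dict[ColumnId, LocalModel]]:
    """Cross-validated base predictions over the whole dataset, plus one
    final local model per (modality, algorithm) trained on all entities.

    Used when interpreting a chosen ensemble variant: the meta layer is fit
    on out-of-fold scores from a stratified k-fold split of all entities,
    while the returned final models (the objects whose features are ranked)
    train on the full entity set, undersampled when configured.
    """
    if not dataset.is_aligned:
        raise ValueError("dataset must be aligned before interpretation")
    labels = dataset.labels
    specs = normalize_roster(config.local_roster)
    entities = labels.entity_ids
    y = labels.labels
    k = config.k_inner
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=derive_seed(config.seed, "interp-folds"))
    columns = sorted((m.name, s.algorithm)
                     for m in dataset.modalities for s in specs)
    scores = np.zeros((len(entities), len(columns)))
    usable = {c: True for c in columns}
    for fold, (tr, te) in enumerate(skf.split(np.asarray(entities), y)):
        train_entities = [entities[i] for i in tr]
        for m in dataset.modalities:
            if config.undersample:
                us_seed = derive_seed(config.seed, "interp-us", fold, m.name)
                fold_train = undersample_majority(train_entities, labels, us_seed)
            else:
                fold_train = train_entities
            eidx = m.entity_index()
            X_tr = m.values[[eidx[e] for e in fold_train]]
            y_tr = labels.subset(fold_train).labels
            X_te = m.values[te]
            for spec in specs:
                col = (m.name, spec.algorithm)
                try:
                    est = spec.build(derive_seed(config.seed, "interp-local",
                                                 fold, m.name, spec.algorithm))
                    est.fit(X_tr, y_tr)
                    scores[te, columns.index(col)] = score_estimator(est, X_te)
                except Exception as exc:  # noqa: BLE001
                    usable[col] = False
                    logger.warning("interpretation fold model %s failed: %s",
                                   col, exc)
    keep = [c for c in columns if usable[c]]
    bpm = BasePredictionMatrix(
        list(entities), keep,
        np.clip(scores[:, [columns.index(c) for c in keep]], 0, 1))

    final_models: dict[ColumnId, LocalModel] = {}
    for m in dataset.modalities:
        if config.undersample:
            train_entities = undersample_majority(
                list(entities), labels,
                derive_seed(config.seed, "interp-final-us", m.name))
        else:
            train_entities = list(entities)
        eidx = m.entity_index()
        X = m.values[[eidx[e] for e in train_entities]]
        y_tr = labels.subset(train_entities).labels
        for spec in specs:
            col = (m.name, spec.algorithm)
            if not usable[col]:
                continue
            model = LocalModel(spec, m.name, -1, -1, list(m.feature_names),
                               list(train_entities))
            try:
                est = spec.build(derive_seed(config.seed, "interp-final",
                                             m.name, spec.algorithm))
                est.fit(X, y_tr)
                model.estimator = est
            except Exception as exc:  # noqa: BLE001
                model.failed = True
                model.failure = str(exc)
                logger.warning("final local model %s failed: %s", col, exc)
                continue
            final_models[col] = model
    return bpm, final_models


def interpret_ei(dataset: MultimodalDataset, best_variant: str,
                 config: RunConfig) -> InterpretationResult:
    """Interpret a chosen ensemble variant retrained on the whole dataset.

    ``best_variant`` is ``"mean"``, ``"ces"`` or ``"stacking:<algorithm>"``
    (typically the best performer from a prior nested-CV run). The chosen
    ensemble is fit on cross-validated base predictions over all entities;
    LFRs are computed for every final local model, the LMR for the ensemble,
    and the two are combined into the rank-product-score table.
    """
    bpm, final_models = full_data_base_predictions(dataset, config)
    drop = [c for c in bpm.column_ids if c not in final_models]
    if drop:
        keep = [c for c in bpm.column_ids if c in final_models]
        bpm = BasePredictionMatrix(
            bpm.entity_ids, keep,
            np.column_stack([bpm.column(c) for c in keep]))
    y = dataset.labels.labels
    if best_variant == "mean":
        ensemble = EnsembleModel("mean", list(bpm.column_ids))
    elif best_variant == "ces":
        ensemble = ces_fit(bpm, y, config.ces_metric, config.ces_max_iterations,
                           config.derive_seed("interp-ces"))
    elif best_variant.startswith("stacking:"):
        algo = best_variant.split(":", 1)[1]
        entry = next((dict(e) if isinstance(e, Mapping) else e
                      for e in config.meta_roster
                      if BaseClassifierSpec.from_entry(e).algorithm == algo),
                     algo)
        ensemble = stacking_fit(bpm, y, BaseClassifierSpec.from_entry(entry)
                                if not isinstance(entry, BaseClassifierSpec)
                                else entry,
                                config.derive_seed("interp-meta", algo))
        if ensemble.failed:
            raise RuntimeError(f"meta-model for {best_variant} failed to train")
    else:
        raise ValueError(f"unknown ensemble variant {best_variant!r}")

    modality_tables = {m.name: m for m in dataset.modalities}
    lfrs = [compute_lfr(model, modality_tables[col[0]], dataset.labels,
                        metric=config.interpretation_metric,
                        cv_folds=config.lfr_cv_folds,
                        seed=config.derive_seed("lfr"))
            for col, model in sorted(final_models.items())]
    lmr = compute_lmr(ensemble, bpm, y, n_permutations=config.n_permutations,
                      seed=config.derive_seed("lmr", best_variant))
    rps = rank_product_scores(lmr, lfrs)
    return InterpretationResult(rps, lmr, lfrs, ensemble)
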