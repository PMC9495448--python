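"""Local-model training under nested cross-validation.

One *local model* is a binary classifier trained on a single data modality.
Under the nested scheme, the dataset is split into ``k_outer`` stratified
outer folds; each outer-training set is further split into ``k_inner``
inner folds on which the local models are trained, so that every base
prediction consumed by the ensemble layer is out-of-fold — produced by a
model whose training set excluded the scored entity.

The classifier registry maps algorithm-family ids to scikit-learn (plus
XGBoost) estimators. Scores come from ``predict_proba`` when available and
a logistic squashing of ``decision_function`` otherwise, so every local
model emits scores in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .data_model import (BasePredictionMatrix, ColumnId, FoldPlan,
                         LabelVector, MultimodalDataset, derive_seed)
from .preprocessing import undersample_majority

logger = logging.getLogger("ensint")


# ---------------------------------------------------------------------------
# Classifier registry
# ---------------------------------------------------------------------------

def _make_registry() -> dict[str, Any]:
    return {
        "adaboost": lambda hp, seed: AdaBoostClassifier(random_state=seed, **hp),
        "decision_tree": lambda hp, seed: DecisionTreeClassifier(random_state=seed, **hp),
        "gradient_boosting": lambda hp, seed: GradientBoostingClassifier(
            random_state=seed, **hp),
        "knn": lambda hp, seed: KNeighborsClassifier(**hp),
        "svm_linear": lambda hp, seed: SVC(kernel="linear", random_state=seed, **hp),
        "random_forest": lambda hp, seed: RandomForestClassifier(random_state=seed, **hp),
        "logistic_regression": lambda hp, seed: LogisticRegression(
            **{"max_iter": 100, **hp}),
        # Rule-list family: an entropy-criterion decision tree is the closest
        # native relative of partial-tree rule induction.
        "rule_based": lambda hp, seed: DecisionTreeClassifier(
            **{"criterion": "entropy", "min_samples_leaf": 2, **hp},
            random_state=seed),
        "naive_bayes": lambda hp, seed: GaussianNB(**hp),
        # Perceptron family; margin squashed through a logistic at score time.
        "perceptron": lambda hp, seed: Perceptron(random_state=seed, **hp),
        "xgboost": lambda hp, seed: XGBClassifier(
            **{"random_state": seed, "eval_metric": "logloss", "verbosity": 0,
               **hp}),
    }


CLASSIFIER_REGISTRY = _make_registry()

#: Default local roster: the ten algorithm families used for local models,
#: with a small SVM regularization constant and capped logistic-regression
#: iterations to bound convergence time.
DEFAULT_LOCAL_ROSTER: list[dict[str, Any]] = [
    {"algorithm": "adaboost"},
    {"algorithm": "decision_tree"},
    {"algorithm": "gradient_boosting"},
    {"algorithm": "knn"},
    {"algorithm": "svm_linear", "hyperparameters": {"C": 0.001}},
    {"algorithm": "random_forest"},
    {"algorithm": "logistic_regression", "hyperparameters": {"max_iter": 100}},
    {"algorithm": "rule_based"},
    {"algorithm": "naive_bayes"},
    {"algorithm": "perceptron"},
]

#: Default meta roster: the nine stacking algorithms (eight sklearn families
#: plus XGBoost); the stacking SVM uses a linear kernel.
DEFAULT_META_ROSTER: list[dict[str, Any]] = [
    {"algorithm": "adaboost"},
    {"algorithm": "decision_tree"},
    {"algorithm": "gradient_boosting"},
    {"algorithm": "knn"},
    {"algorithm": "svm_linear"},
    {"algorithm": "random_forest"},
    {"algorithm": "logistic_regression"},
    {"algorithm": "naive_bayes"},
    {"algorithm": "xgboost"},
]


@dataclass(frozen=True)
class BaseClassifierSpec:
    """An algorithm-family id plus hyperparameter overrides."""

    algorithm: str
    hyperparameters: tuple[tuple[str, Any], ...] = ()

    def __post_init__(self) -> None:
        if self.algorithm not in CLASSIFIER_REGISTRY:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; registered: "
                f"{sorted(CLASSIFIER_REGISTRY)}")
        # Instantiating validates hyperparameter names per algorithm.
        try:
            self.build(seed=0)
        except TypeError as exc:
            raise ValueError(
                f"invalid hyperparameters for {self.algorithm!r}: {exc}") from exc

    @classmethod
    def from_entry(cls, entry: str | Mapping[str, Any]) -> "BaseClassifierSpec":
        if isinstance(entry, str):
            return cls(entry)
        hp = entry.get("hyperparameters", {}) or {}
        return cls(entry["algorithm"], tuple(sorted(hp.items())))

    def build(self, seed: int = 0) -> BaseEstimator:
        return CLASSIFIER_REGISTRY[self.algorithm](dict(self.hyperparameters), seed)


def normalize_roster(roster: Sequence[str | Mapping[str, Any]],
                     ) -> list[BaseClassifierSpec]:
    specs = [BaseClassifierSpec.from_entry(e) for e in roster]
    ids = [s.algorithm for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate algorithm ids in roster")
    return specs


def score_estimator(est: BaseEstimator, X: np.ndarray) -> np.ndarray:
    """Uniform [0,1] scoring: positive-class probability, or the logistic
    squashing of the decision margin for margin-only estimators."""
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        pos = list(est.classes_).index(1) if 1 in est.classes_ else -1
        s = proba[:, pos]
    else:
        margin = est.decision_function(X)
        if 1 in est.classes_ and list(est.classes_).index(1) == 0:
            margin = -margin
        s = expit(margin)
    return np.clip(np.asarray(s, dtype=float), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Local models
# ---------------------------------------------------------------------------

@dataclass
class LocalModel:
    """One fitted local classifier: (outer fold, inner fold, modality, algorithm)."""

    spec: BaseClassifierSpec
    modality: str
    outer_fold: int
    inner_fold: int
    feature_names: list[str]
    train_entities: list[str]
    estimator: BaseEstimator | None = None
    failed: bool = False
    failure: str = ""

    @property
    def key(self) -> tuple[int, int, str, str]:
        return (self.outer_fold, self.inner_fold, self.modality, self.spec.algorithm)

    @property
    def column(self) -> ColumnId:
        return (self.modality, self.spec.algorithm)

    def score(self, X: np.ndarray) -> np.ndarray:
        if self.failed or self.estimator is None:
            raise RuntimeError(f"model {self.key} failed to train")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"model {self.key} expects {len(self.feature_names)} features, "
                f"got shape {X.shape}")
        return score_estimator(self.estimator, X)


LocalModelCollection = dict[tuple[int, int, str, str], LocalModel]


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

def make_fold_plan(labels: LabelVector, k_outer: int = 5, k_inner: int = 5,
                   seed: int = 0) -> FoldPlan:
    """Stratified nested fold assignments, deterministic under ``seed``.

    Outer folds partition the entities with per-fold positive counts within
    one of perfect stratification; each outer-training set is further
    partitioned into ``k_inner`` stratified inner folds.
    """
    labels.require_both_classes()
    if labels.n_pos < k_outer:
        raise ValueError(
            f"{labels.n_pos} positives cannot be stratified into {k_outer} "
            f"outer folds; reduce k_outer")
    entities = np.asarray(labels.entity_ids)
    y = labels.labels
    outer_assignment: dict[str, int] = {}
    skf = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed % (2**31))
    for fold, (_, test_idx) in enumerate(skf.split(entities, y)):
        for i in test_idx:
            outer_assignment[str(entities[i])] = fold
    inner_assignment: dict[tuple[int, str], int] = {}
    for o in range(k_outer):
        train_idx = np.flatnonzero([outer_assignment[str(e)] != o for e in entities])
        y_tr = y[train_idx]
        if y_tr.sum() < k_inner:
            raise ValueError(
                f"outer fold {o}: {int(y_tr.sum())} positives cannot be "
                f"stratified into {k_inner} inner folds; reduce k_inner")
        inner_seed = derive_seed(seed, "inner", o)
        skf_in = StratifiedKFold(n_splits=k_inner, shuffle=True,
                                 random_state=inner_seed)
        for fold, (_, test_idx) in enumerate(skf_in.split(train_idx, y_tr)):
            for i in test_idx:
                inner_assignment[(o, str(entities[train_idx[i]]))] = fold
    return FoldPlan(k_outer, k_inner, outer_assignment, inner_assignment, seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_local_models(dataset: MultimodalDataset, plan: FoldPlan,
                       roster: Sequence[str | Mapping[str, Any]] | Sequence[BaseClassifierSpec],
                       undersample: bool = True, seed: int = 0,
                       ) -> LocalModelCollection:
    """Fit one local model per (outer fold, inner fold, modality, algorithm).

    Each model trains on the inner-training entities of its fold pair, with
    the majority class undersampled to balance (shared subset across the
    algorithms of a modality) when ``undersample`` is set. A model whose fit
    raises is recorded as failed; its column is dropped downstream with a
    warning.
    """
    if not dataset.is_aligned:
        raise ValueError("dataset must be aligned (align_entities) before training")
    specs = (list(roster) if roster and isinstance(roster[0], BaseClassifierSpec)
             else normalize_roster(roster))  # type: ignore[arg-type]
    labels = dataset.labels
    models: LocalModelCollection = {}
    for o in range(plan.k_outer):
        for i in range(plan.k_inner):
            base_train = plan.inner_train(o, i)
            for m in dataset.modalities:
                if undersample:
                    us_seed = derive_seed(seed, "undersample", o, i, m.name)
                    train_entities = undersample_majority(base_train, labels, us_seed)
                else:
                    train_entities = list(base_train)
                idx = [m.entity_index()[e] for e in train_entities]
                X = m.values[idx]
                y = labels.subset(train_entities).labels
                for spec in specs:
                    model_seed = derive_seed(seed, "local", o, i, m.name,
                                             spec.algorithm)
                    model = LocalModel(spec, m.name, o, i,
                                       list(m.feature_names),
                                       list(train_entities))
                    try:
                        est = spec.build(model_seed)
                        est.fit(X, y)
                        model.estimator = est
                    except Exception as exc:  # noqa: BLE001 — contract: record, drop
                        model.failed = True
                        model.failure = f"{type(exc).__name__}: {exc}"
                        logger.warning("local model %s failed: %s", model.key,
                                       model.failure)
                    models[model.key] = model
    return models


def failed_columns(models: LocalModelCollection) -> set[ColumnId]:
    return {m.column for m in models.values() if m.failed}


# ---------------------------------------------------------------------------
# Base prediction matrices
# ---------------------------------------------------------------------------

def generate_base_predictions(models: LocalModelCollection,
                              dataset: MultimodalDataset, plan: FoldPlan,
                              ) -> tuple[dict[int, BasePredictionMatrix],
                                         dict[int, BasePredictionMatrix]]:
    """Produce per-outer-fold train/test base prediction matrices.

    Train matrix: every outer-training entity is scored, per column, by the
    inner-fold model that held it out. Test matrix: every outer-test entity
    is scored by the mean of that column's ``k_inner`` inner models, keeping
    train and test base scores on the same distributional footing. Columns
    with any failed model are dropped globally with a warning.
    """
    bad = failed_columns(models)
    if bad:
        logger.warning("dropping %d column(s) with failed models: %s",
                       len(bad), sorted(bad))
    columns = sorted({m.column for m in models.values()} - bad)
    if not columns:
        raise ValueError("no usable local-model columns")
    modality_tables = {m.name: m for m in dataset.modalities}
    train_bpms: dict[int, BasePredictionMatrix] = {}
    test_bpms: dict[int, BasePredictionMatrix] = {}
    for o in range(plan.k_outer):
        train_entities = sorted(plan.outer_train(o))
        test_entities = sorted(plan.outer_test(o))
        train_scores = np.empty((len(train_entities), len(columns)))
        test_scores = np.empty((len(test_entities), len(columns)))
        train_prov: dict[ColumnId, dict[str, Any]] = {c: {} for c in columns}
        test_prov: dict[ColumnId, dict[str, Any]] = {c: {} for c in columns}
        train_pos = {e: r for r, e in enumerate(train_entities)}
        for ci, (mod, algo) in enumerate(columns):
            table = modality_tables[mod]
            eidx = table.entity_index()
            X_test = table.values[[eidx[e] for e in test_entities]]
            inner_scores = np.zeros((len(test_entities), plan.k_inner))
            for i in range(plan.k_inner):
                model = models[(o, i, mod, algo)]
                held_out = plan.inner_test(o, i)
                X_in = table.values[[eidx[e] for e in held_out]]
                s = model.score(X_in)
                for e, val in zip(held_out, s):
                    train_scores[train_pos[e], ci] = val
                    train_prov[(mod, algo)][e] = model.key
                inner_scores[:, i] = model.score(X_test)
            test_scores[:, ci] = inner_scores.mean(axis=1)
            for e in test_entities:
                test_prov[(mod, algo)][e] = tuple(
                    models[(o, i, mod, algo)].key for i in range(plan.k_inner))
        train_bpms[o] = BasePredictionMatrix(train_entities, list(columns),
                                             np.clip(train_scores, 0, 1), train_prov)
        test_bpms[o] = BasePredictionMatrix(test_entities, list(columns),
                                            np.clip(test_scores, 0, 1), test_prov)
    return train_bpms, test_bpms


def audit_out_of_fold(bpm: BasePredictionMatrix,
                      models: LocalModelCollection) -> None:
    """Verify the out-of-fold contract: no score in ``bpm`` was produced by a
    model whose training set contained the scored entity. Raises on breach."""
    for col, prov in bpm.provenance.items():
        for entity, keys in prov.items():
            # A single model key is a 4-tuple; multi-model provenance (test
            # rows) is a tuple of such keys.
            if keys and isinstance(keys[0], tuple):
                key_list = keys
            else:
                key_list = (keys,)
            for key in key_list:
                if entity in models[key].train_entities:
                    raise AssertionError(
                        f"out-of-fold breach: entity {entity!r} scored by model "
                        f"{key} trained on it (column {col})")


# ---------------------------------------------------------------------------
# Early-integration (concatenation) baseline
# ---------------------------------------------------------------------------

def train_early_baseline(dataset: MultimodalDataset, plan: FoldPlan,
                         spec: str | Mapping[str, Any] | BaseClassifierSpec = "xgboost",
                         seed: int = 0,
                         ) -> dict[int, tuple[list[str], np.ndarray]]:
    """Concatenation baseline: features joined across modalities in modality
    order, one model per outer fold trained on the outer-training set.

    Returns ``{outer_fold: (test_entity_ids, scores)}``. Duplicate feature
    columns across modalities are accepted as-is (no deduplication).
    """
    if not dataset.is_aligned:
        raise ValueError("dataset must be aligned before training")
    if not isinstance(spec, BaseClassifierSpec):
        spec = BaseClassifierSpec.from_entry(spec)
    X_full = np.hstack([m.values for m in dataset.modalities])
    order = dataset.labels.entity_ids
    pos = {e: i for i, e in enumerate(order)}
    y_all = dataset.labels.labels
    out: dict[int, tuple[list[str], np.ndarray]] = {}
    for o in range(plan.k_outer):
        train = sorted(plan.outer_train(o))
        test = sorted(plan.outer_test(o))
        est = spec.build(derive_seed(seed, "early", o))
        est.fit(X_full[[pos[e] for e in train]],
                y_all[[pos[e] for e in train]])
        out[o] = (test, score_estimator(est, X_full[[pos[e] for e in test]]))
    return out
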