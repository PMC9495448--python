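"""Preprocessing applied before local-model training.

Implements the clinical-table pipeline (missingness filter, KNN imputation,
one-hot encoding, train-fitted z-scoring), the network-modality construction
(adjacency vectors from a weighted edge list), and training-fold class
balancing by random undersampling of the majority class.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import LabelVector, ModalityTable

logger = logging.getLogger("ensint")


# ---------------------------------------------------------------------------
# Missingness filter
# ---------------------------------------------------------------------------

def filter_missing_features(table: ModalityTable,
                            max_missing_frac: float = 0.3) -> ModalityTable:
    """Keep only features with a missing fraction strictly below the cutoff.

    The inequality is strict ("fewer than 30% missing"): a feature missing in
    exactly ``max_missing_frac`` of entities is dropped. Survivor order is
    preserved. Raises if nothing survives.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = table.missing_mask.mean(axis=0)
    keep = np.flatnonzero(frac < max_missing_frac)
    if keep.size == 0:
        raise ValueError(
            f"modality {table.name!r}: all features exceed the missingness cutoff")
    return ModalityTable(
        table.name,
        list(table.entity_ids),
        [table.feature_names[j] for j in keep],
        table.values[:, keep],
        table.missing_mask[:, keep],
    )


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

def knn_impute(table: ModalityTable, k: int = 5) -> ModalityTable:
    """Impute missing cells by the mean over the k nearest donor rows.

    Distance between two rows is Euclidean over their mutually observed
    features, scaled by ``sqrt(n_features / n_usable)`` so rows with few
    shared features are not artificially close. Donors for a missing cell
    are restricted to rows where that feature is observed; distance ties are
    broken by entity order. Observed cells are left bit-identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = table.missing_mask
    zero_obs = np.flatnonzero((~mask).sum(axis=0) == 0)
    if zero_obs.size:
        bad = [table.feature_names[j] for j in zero_obs]
        raise ValueError(
            f"modality {table.name!r}: feature(s) with no observed values "
            f"{bad[:5]} — filter before imputing")
    if not mask.any():
        return table

    X = table.values.copy()
    X[mask] = np.nan
    n, p = X.shape
    observed = ~mask

    # Pairwise distances with missing-aware scaling.
    dist = np.full((n, n), np.inf)
    for i in range(n):
        both = observed[i] & observed
        diff = np.where(both, X[i] - X, 0.0)
        usable = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt(np.where(usable > 0, (diff**2).sum(axis=1) * p / usable, np.inf))
        dist[i] = d
    np.fill_diagonal(dist, np.inf)

    out = table.values.copy()
    for i, j in zip(*np.nonzero(mask)):
        donors = np.flatnonzero(observed[:, j])
        donors = donors[donors != i]
        if donors.size == 0:  # unreachable given the zero_obs check
            raise ValueError("no donor rows")
        order = donors[np.argsort(dist[i, donors], kind="stable")]
        chosen = order[: min(k, order.size)]
        finite = chosen[np.isfinite(dist[i, chosen])]
        if finite.size:
            chosen = finite
        out[i, j] = X[chosen, j].mean()
    return ModalityTable(table.name, list(table.entity_ids),
                         list(table.feature_names), out,
                         np.zeros_like(mask))


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

class OneHotEncoding:
    """Train-fitted one-hot expansion of selected categorical features.

    Levels are learned from observed values at fit time; an unseen level at
    transform time yields an all-zero indicator row (logged). Indicator
    columns are named ``feature=level``; non-categorical columns pass
    through untouched, in their original relative order (categorical blocks
    expand in place).
    """

    def __init__(self, categorical_features: Sequence[str]):
        self.categorical_features = list(categorical_features)
        self.levels_: dict[str, list[str]] = {}

    def fit(self, table: ModalityTable) -> "OneHotEncoding":
        missing = set(self.categorical_features) - set(table.feature_names)
        if missing:
            raise ValueError(f"categorical feature(s) not in table: {sorted(missing)}")
        for f in self.categorical_features:
            j = table.feature_names.index(f)
            obs = table.values[~table.missing_mask[:, j], j]
            self.levels_[f] = [_level_token(v) for v in sorted(set(obs))]
        return self

    def transform(self, table: ModalityTable) -> ModalityTable:
        if not self.levels_:
            raise RuntimeError("encoder not fitted")
        cols: list[str] = []
        vals: list[np.ndarray] = []
        mask: list[np.ndarray] = []
        for j, f in enumerate(table.feature_names):
            if f in self.levels_:
                col_mask = table.missing_mask[:, j]
                tokens = np.array([_level_token(v) for v in table.values[:, j]])
                unseen = (~col_mask) & ~np.isin(tokens, self.levels_[f])
                if unseen.any():
                    logger.warning("one-hot: %d row(s) with unseen level(s) in %r",
                                   int(unseen.sum()), f)
                for level in self.levels_[f]:
                    cols.append(f"{f}={level}")
                    ind = ((tokens == level) & ~col_mask).astype(float)
                    vals.append(ind)
                    mask.append(col_mask.copy())
            else:
                cols.append(f)
                vals.append(table.values[:, j])
                mask.append(table.missing_mask[:, j])
        return ModalityTable(table.name, list(table.entity_ids), cols,
                             np.column_stack(vals), np.column_stack(mask))


def _level_token(value: float) -> str:
    v = float(value)
    return str(int(v)) if v == int(v) else repr(v)


def one_hot_encode(table: ModalityTable, categorical_features: Sequence[str],
                   encoder: OneHotEncoding | None = None,
                   ) -> tuple[ModalityTable, OneHotEncoding]:
    """One-hot encode ``table``; fit a new encoder unless one is supplied."""
    if encoder is None:
        encoder = OneHotEncoding(categorical_features).fit(table)
    return encoder.transform(table), encoder


# ---------------------------------------------------------------------------
# z-score normalization
# ---------------------------------------------------------------------------

def zscore_normalize(train: ModalityTable,
                     apply_to: ModalityTable | None = None) -> ModalityTable:
    """Normalize features to z-scores with statistics fitted on ``train``.

    Uses the population standard deviation (divisor n over observed training
    cells); zero-variance features map to 0 everywhere. Statistics are never
    fitted on ``apply_to``, preventing train/test leakage.
    """
    if apply_to is None:
        apply_to = train
    if train.feature_names != apply_to.feature_names:
        raise ValueError("train and apply_to feature names differ")
    tv = np.where(train.missing_mask, np.nan, train.values)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(tv, axis=0)
        sd = np.nanstd(tv, axis=0)  # population (divisor n)
    out = apply_to.values.copy()
    nonzero = sd > 0
    out[:, nonzero] = (out[:, nonzero] - mean[nonzero]) / sd[nonzero]
    out[:, ~nonzero] = 0.0
    out[apply_to.missing_mask] = np.nan
    return ModalityTable(apply_to.name, list(apply_to.entity_ids),
                         list(apply_to.feature_names), out,
                         apply_to.missing_mask.copy())


# ---------------------------------------------------------------------------
# Adjacency-vector modality from a weighted edge list
# ---------------------------------------------------------------------------

def adjacency_features(edges: Sequence[tuple[str, str, float]],
                       node_universe: Sequence[str],
                       name: str = "network") -> ModalityTable:
    """Build the adjacency-vector modality of an undirected weighted graph.

    Each entity's feature vector is its row of the symmetric adjacency
    matrix over ``node_universe`` (feature j of entity i = edge weight
    between them, 0 when absent, so isolated nodes get all-zero rows).
    Edges with an endpoint outside the universe are dropped with a log
    message; negative weights or conflicting duplicate weights are errors.
    """
    nodes = list(dict.fromkeys(str(n) for n in node_universe))
    index = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    seen: dict[tuple[int, int], float] = {}
    dropped = 0
    for a, b, w in edges:
        w = float(w)
        if w < 0:
            raise ValueError(f"negative edge weight {w} on ({a}, {b})")
        if str(a) not in index or str(b) not in index:
            dropped += 1
            continue
        i, j = index[str(a)], index[str(b)]
        key = (min(i, j), max(i, j))
        if key in seen and seen[key] != w:
            raise ValueError(f"conflicting duplicate edge ({a}, {b}): "
                             f"{seen[key]} vs {w}")
        seen[key] = w
        A[i, j] = A[j, i] = w
    if dropped:
        logger.warning("adjacency_features: dropped %d edge(s) outside the universe",
                       dropped)
    return ModalityTable(name, nodes, nodes, A, np.zeros_like(A, dtype=bool))


def read_edge_list(path: str | Path, sep: str = "\t",
                   ) -> list[tuple[str, str, float]]:
    """Read an undirected weighted edge list (node_a, node_b, weight)."""
    df = pd.read_csv(Path(path), sep=sep, header=None,
                     names=["node_a", "node_b", "weight"],
                     dtype={"node_a": str, "node_b": str})
    return [(r.node_a, r.node_b, float(r.weight)) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# Undersampling
# ---------------------------------------------------------------------------

def undersample_majority(entity_ids: Sequence[str], labels: LabelVector,
                         seed: int) -> list[str]:
    """Balance classes by subsampling the majority class without replacement.

    All minority-class entities are kept; the majority class is randomly
    reduced to the minority count. The returned subset preserves the input
    entity order and is deterministic under ``seed``. Applied inside
    training folds only — test folds keep the natural class ratio.
    """
    entity_ids = [str(e) for e in entity_ids]
    y = labels.subset(entity_ids).labels
    pos = [e for e, l in zip(entity_ids, y) if l == 1]
    neg = [e for e, l in zip(entity_ids, y) if l == 0]
    if not pos or not neg:
        raise ValueError("undersampling needs both classes present")
    if len(pos) == len(neg):
        return entity_ids
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    kept_majority = set(rng.choice(len(majority), size=len(minority),
                                   replace=False).tolist())
    keep = set(minority) | {majority[i] for i in kept_majority}
    return [e for e in entity_ids if e in keep]
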