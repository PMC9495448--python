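"""Core data containers and delimited-text IO for Ensemble Integration.

The central objects are :class:`ModalityTable` (one numeric feature table per
data modality, with an explicit missingness mask), :class:`LabelVector`
(binary outcome per entity), :class:`MultimodalDataset` (the aligned bundle
the pipeline consumes), :class:`FoldPlan` (nested cross-validation
assignments) and :class:`BasePredictionMatrix` (the out-of-fold local-model
scores that form the ensemble layer's feature space).

All tables are read and written as delimited text with a header row whose
first column is ``entity_id``. Scores are serialised with 17 significant
digits so that write/read round-trips are lossless for float64.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ensint")

#: Cell tokens treated as missing when parsing modality tables.
NA_TOKENS = ("", "NA", "NaN", "nan", "null")

#: Float format used by all writers; 17 significant digits round-trip float64.
FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Modality tables
# ---------------------------------------------------------------------------

@dataclass
class ModalityTable:
    """A named numeric matrix (entities x features) with a missingness mask.

    Parameters
    ----------
    name : str
        Modality identifier (e.g. ``"laboratory_tests"`` or ``"coexpression"``).
    entity_ids : list of str
        Ordered, unique row identifiers.
    feature_names : list of str
        Ordered, unique column identifiers.
    values : ndarray of shape (n_entities, n_features)
        Numeric data; entries under the mask are ignored (stored as NaN).
    missing_mask : ndarray of bool, same shape
        True where the cell is missing.
    """

    name: str
    entity_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"modality {self.name!r}: values must be 2-D")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.entity_ids = [str(e) for e in self.entity_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError(f"modality {self.name!r}: needs >=1 entity and >=1 feature")
        if len(self.entity_ids) != n or len(self.feature_names) != p:
            raise ValueError(f"modality {self.name!r}: id/shape mismatch")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError(f"modality {self.name!r}: mask/value shape mismatch")
        if len(set(self.entity_ids)) != n:
            raise ValueError(f"modality {self.name!r}: duplicate entity ids")
        if len(set(self.feature_names)) != p:
            raise ValueError(f"modality {self.name!r}: duplicate feature names")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError(f"modality {self.name!r}: non-finite observed value")

    # -- convenience -------------------------------------------------------
    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def entity_index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.entity_ids)}

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.entity_index()[entity_id]]

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.entity_ids, columns=self.feature_names)

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "ModalityTable":
        values = frame.to_numpy(dtype=float)
        return cls(
            name=name,
            entity_ids=[str(i) for i in frame.index],
            feature_names=[str(c) for c in frame.columns],
            values=values,
            missing_mask=np.isnan(values),
        )


def read_modality_table(path: str | Path, name: str | None = None,
                        sep: str | None = None) -> ModalityTable:
    """Read a modality table from delimited text.

    The first column must hold entity IDs and the header row the feature
    names. Cells equal to one of :data:`NA_TOKENS` are flagged missing; any
    other non-numeric cell is a hard error naming the offending row/column.
    The delimiter is inferred from the suffix (``.csv`` -> comma, else tab)
    unless ``sep`` is given.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an entity-id column plus >=1 feature")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no entities")
    entity_ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(entity_ids)) != len(entity_ids):
        dupes = sorted({e for e in entity_ids if entity_ids.count(e) > 1})
        raise ValueError(f"{path}: duplicate entity ids {dupes[:5]}")
    feature_names = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    mask = np.zeros(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell in NA_TOKENS:
                values[i, j] = np.nan
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at entity "
                        f"{entity_ids[i]!r}, feature {feature_names[j]!r}"
                    ) from exc
    return ModalityTable(name or path.stem, entity_ids, feature_names, values, mask)


def write_modality_table(table: ModalityTable, path: str | Path,
                         sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = table.to_frame()
    df.index.name = "entity_id"
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT, na_rep="NA")


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

@dataclass
class LabelVector:
    """Binary labels over an ordered set of entities; 1 = positive class."""

    entity_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.entity_ids = [str(e) for e in self.entity_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.entity_ids):
            raise ValueError("labels must be 1-D and match entity_ids")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids in labels")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.entity_ids)

    def subset(self, entity_ids: Sequence[str]) -> "LabelVector":
        s = self.as_series()
        return LabelVector(list(entity_ids), s.loc[list(entity_ids)].to_numpy())

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError("need at least one positive and one negative label")


def read_labels(path: str | Path, sep: str | None = None) -> LabelVector:
    """Read a label file (columns ``entity_id``, ``label``)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    return LabelVector(df.iloc[:, 0].tolist(), df.iloc[:, 1].to_numpy())


def write_labels(labels: LabelVector, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame({"entity_id": labels.entity_ids, "label": labels.labels}).to_csv(
        Path(path), sep=sep, index=False)


# ---------------------------------------------------------------------------
# Multimodal dataset and alignment
# ---------------------------------------------------------------------------

@dataclass
class MultimodalDataset:
    """A bundle of modality tables plus labels over a shared entity universe."""

    modalities: list[ModalityTable]
    labels: LabelVector

    def __post_init__(self) -> None:
        names = [m.name for m in self.modalities]
        if len(set(names)) != len(names):
            raise ValueError("duplicate modality names")

    @property
    def entity_universe(self) -> list[str]:
        seen: dict[str, None] = dict.fromkeys(self.labels.entity_ids)
        for m in self.modalities:
            seen.update(dict.fromkeys(m.entity_ids))
        return list(seen)

    def modality(self, name: str) -> ModalityTable:
        for m in self.modalities:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def is_aligned(self) -> bool:
        ref = self.labels.entity_ids
        return all(m.entity_ids == ref for m in self.modalities)

    def restrict_modalities(self, names: Sequence[str]) -> "MultimodalDataset":
        return MultimodalDataset([self.modality(n) for n in names], self.labels)


def align_entities(dataset: MultimodalDataset) -> MultimodalDataset:
    """Reindex every modality to the labeled entities, in lexicographic order.

    Entities absent from a modality receive an all-zero feature row with the
    missing mask false: in network-derived modalities an absent entity simply
    has no associations, so zeros are data, not missingness. Entities present
    in a modality but unlabeled are dropped. A labeled entity found in no
    modality at all is retained (zero-filled everywhere) with a warning.
    """
    canonical = sorted(dict.fromkeys(dataset.labels.entity_ids))
    labels = dataset.labels.subset(canonical)
    covered: set[str] = set()
    for m in dataset.modalities:
        covered.update(m.entity_ids)
    orphans = [e for e in canonical if e not in covered]
    if orphans:
        logger.warning(
            "%d labeled entities appear in no modality; retained zero-filled: %s%s",
            len(orphans), orphans[:5], "..." if len(orphans) > 5 else "")
    aligned = []
    for m in dataset.modalities:
        idx = m.entity_index()
        values = np.zeros((len(canonical), m.n_features))
        mask = np.zeros_like(values, dtype=bool)
        for i, e in enumerate(canonical):
            if e in idx:
                values[i] = m.values[idx[e]]
                mask[i] = m.missing_mask[idx[e]]
        aligned.append(ModalityTable(m.name, list(canonical), list(m.feature_names),
                                     values, mask))
    return MultimodalDataset(aligned, labels)


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Nested cross-validation assignments.

    ``outer_assignment`` maps entity -> outer fold index (0..k_outer-1);
    ``inner_assignment`` maps (outer fold, entity) -> inner fold index for
    every entity in that outer fold's training set.
    """

    k_outer: int
    k_inner: int
    outer_assignment: dict[str, int]
    inner_assignment: dict[tuple[int, str], int]
    seed: int

    def outer_test(self, fold: int) -> list[str]:
        return [e for e, f in self.outer_assignment.items() if f == fold]

    def outer_train(self, fold: int) -> list[str]:
        return [e for e, f in self.outer_assignment.items() if f != fold]

    def inner_test(self, outer: int, inner: int) -> list[str]:
        return [e for e in self.outer_train(outer)
                if self.inner_assignment[(outer, e)] == inner]

    def inner_train(self, outer: int, inner: int) -> list[str]:
        return [e for e in self.outer_train(outer)
                if self.inner_assignment[(outer, e)] != inner]

    def validate(self, labels: LabelVector | None = None) -> None:
        """Check the partition invariants (and stratification when labels given)."""
        entities = set(self.outer_assignment)
        folds = set(self.outer_assignment.values())
        if folds - set(range(self.k_outer)):
            raise ValueError("outer fold index out of range")
        for o in range(self.k_outer):
            train = set(self.outer_train(o))
            inner_entities = {e for (oo, e) in self.inner_assignment if oo == o}
            if inner_entities != train:
                raise ValueError(f"inner folds of outer {o} do not cover its training set")
            test = set(self.outer_test(o))
            if test & inner_entities:
                raise ValueError(f"outer-test entity inside inner folds of outer {o}")
        if labels is not None:
            s = labels.as_series()
            pos = [sum(s[e] for e in self.outer_test(o)) for o in range(self.k_outer)]
            if max(pos) - min(pos) > 1:
                raise ValueError("outer folds not stratified within +/-1 positive")
        if set().union(*(set(self.outer_test(o)) for o in range(self.k_outer))) != entities:
            raise ValueError("outer folds do not partition the entity set")


def write_fold_plan(plan: FoldPlan, path: str | Path) -> None:
    rows = []
    for e, o in sorted(plan.outer_assignment.items()):
        for oo in range(plan.k_outer):
            if oo == o:
                continue
            rows.append({"entity_id": e, "outer_fold": oo,
                         "inner_fold": plan.inner_assignment[(oo, e)]})
        rows.append({"entity_id": e, "outer_fold": o, "inner_fold": -1})
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def read_fold_plan(path: str | Path, seed: int = 0) -> FoldPlan:
    df = pd.read_csv(Path(path), sep="\t", dtype={"entity_id": str})
    k_outer = int(df["outer_fold"].max()) + 1
    k_inner = int(df["inner_fold"].max()) + 1
    outer = {}
    inner = {}
    for rec in df.itertuples(index=False):
        if rec.inner_fold == -1:
            outer[rec.entity_id] = int(rec.outer_fold)
        else:
            inner[(int(rec.outer_fold), rec.entity_id)] = int(rec.inner_fold)
    return FoldPlan(k_outer, k_inner, outer, inner, seed)


# ---------------------------------------------------------------------------
# Base prediction matrices
# ---------------------------------------------------------------------------

ColumnId = tuple[str, str]  # (modality, algorithm)


def column_label(col: ColumnId) -> str:
    return f"{col[0]}|{col[1]}"


def parse_column_label(label: str) -> ColumnId:
    modality, algorithm = label.split("|", 1)
    return modality, algorithm


@dataclass
class BasePredictionMatrix:
    """Out-of-fold local-model scores: rows = entities, columns = local models.

    ``provenance`` maps each column to ``{entity_id: model_key}`` recording
    which fitted local model produced each score; model keys index into the
    collection returned by the training stage so the out-of-fold contract can
    be audited after the fact.
    """

    entity_ids: list[str]
    column_ids: list[ColumnId]
    scores: np.ndarray
    provenance: dict[ColumnId, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.entity_ids), len(self.column_ids)):
            raise ValueError("scores shape mismatch")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    def column(self, col: ColumnId) -> np.ndarray:
        return self.scores[:, self.column_ids.index(col)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.entity_ids,
                            columns=[column_label(c) for c in self.column_ids])


def write_predictions(bpm: BasePredictionMatrix, path: str | Path) -> None:
    """Write a prediction matrix as TSV (plus a JSON provenance sidecar)."""
    path = Path(path)
    df = bpm.to_frame()
    df.index.name = "entity_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    if bpm.provenance:
        sidecar = {column_label(c): {e: str(k) for e, k in prov.items()}
                   for c, prov in bpm.provenance.items()}
        path.with_suffix(path.suffix + ".provenance.json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True))


def read_predictions(path: str | Path) -> BasePredictionMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    return BasePredictionMatrix(
        entity_ids=list(df.index),
        column_ids=[parse_column_label(c) for c in df.columns],
        scores=df.to_numpy(dtype=float),
    )


def write_rps_table(rps: pd.DataFrame, path: str | Path) -> None:
    """Write a rank-product-score table (``modality``, ``feature``, ``rps``),
    sorted ascending (smaller RPS = more important)."""
    expected = ["modality", "feature", "rps"]
    if list(rps.columns) != expected:
        rps = rps[expected]
    rps = rps.sort_values(["rps", "modality", "feature"], kind="stable")
    rps.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FMT)


def read_rps_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t",
                       dtype={"modality": str, "feature": str},
                       float_precision="round_trip")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "seed", "k_outer", "k_inner", "undersample", "local_roster", "meta_roster",
    "ces", "interpretation", "paths",
}
_CES_KEYS = {"metric", "max_iterations"}
_INTERP_KEYS = {"n_permutations", "metric", "lfr_cv_folds"}


@dataclass
class RunConfig:
    """Run configuration: classifier rosters, CV granularity, seeds, knobs.

    ``local_roster`` / ``meta_roster`` entries are either an algorithm id
    string or a mapping ``{algorithm: ..., hyperparameters: {...}}``.
    """

    seed: int = 0
    k_outer: int = 5
    k_inner: int = 5
    undersample: bool = True
    local_roster: list[Any] = None  # type: ignore[assignment]
    meta_roster: list[Any] = None  # type: ignore[assignment]
    ces_metric: str = "fmax"
    ces_max_iterations: int = 100
    n_permutations: int = 100
    interpretation_metric: str = "auprc"
    lfr_cv_folds: int = 5
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        from .local_layer import DEFAULT_LOCAL_ROSTER, DEFAULT_META_ROSTER
        if self.local_roster is None:
            self.local_roster = [dict(r) for r in DEFAULT_LOCAL_ROSTER]
        if self.meta_roster is None:
            self.meta_roster = [dict(r) for r in DEFAULT_META_ROSTER]
        if not self.local_roster or not self.meta_roster:
            raise ValueError("classifier rosters must be non-empty")
        self.seed = int(self.seed)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key in ("seed", "k_outer", "k_inner", "undersample",
                    "local_roster", "meta_roster", "paths"):
            if key in raw:
                kwargs[key] = raw[key]
        ces = raw.get("ces", {})
        if set(ces) - _CES_KEYS:
            raise ValueError(f"unknown ces key(s): {sorted(set(ces) - _CES_KEYS)}")
        if "metric" in ces:
            kwargs["ces_metric"] = ces["metric"]
        if "max_iterations" in ces:
            kwargs["ces_max_iterations"] = int(ces["max_iterations"])
        interp = raw.get("interpretation", {})
        if set(interp) - _INTERP_KEYS:
            raise ValueError(
                f"unknown interpretation key(s): {sorted(set(interp) - _INTERP_KEYS)}")
        if "n_permutations" in interp:
            kwargs["n_permutations"] = int(interp["n_permutations"])
        if "metric" in interp:
            kwargs["interpretation_metric"] = interp["metric"]
        if "lfr_cv_folds" in interp:
            kwargs["lfr_cv_folds"] = int(interp["lfr_cv_folds"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_mapping(raw or {})

    def derive_seed(self, *components: Any) -> int:
        """Derive a reproducible sub-seed (< 2**31) from the global seed and a
        component path, via a stable blake2 hash."""
        return derive_seed(self.seed, *components)

    def replace(self, **kwargs: Any) -> "RunConfig":
        return replace(self, **kwargs)


def derive_seed(global_seed: int, *components: Any) -> int:
    import hashlib

    payload = "\x1f".join([str(global_seed)] + [str(c) for c in components])
    digest = hashlib.blake2b(payload.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)
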