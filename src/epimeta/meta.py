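"""Meta-classifier integration of per-residue interface-likelihood scores.

Each base classifier supplies one score in [0,1] per antigen residue.  The
score tracks are min-max normalized per antigen, assembled into a feature
table aligned with the structure's residue order, and integrated by a
gradient-boosted tree ensemble (XGBoost) trained on contact-annotated
antigens, producing a consensus interface-likelihood score per residue.

Cross-validation folds hold antigens (never residues) together, and are
stratified by antigen-size tertile so each fold sees a similar size
distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

from . import io
from .structure import AntigenStructure, ResidueId

log = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Per-residue score vectors for one antigen, one column per classifier."""

    antigen_id: str
    residues: list[ResidueId]
    scores: pd.DataFrame                  # columns = classifier names
    labels: np.ndarray | None = None      # 1 = epitopal, aligned with residues

    def __post_init__(self):
        if len(self.scores) != len(self.residues):
            raise ValueError("score rows must match residue count")

    @property
    def classifiers(self) -> list[str]:
        return list(self.scores.columns)

    def with_labels(self, annotation) -> "ScoreTable":
        """Attach binary labels from an epitope annotation (residue set)."""
        residues = getattr(annotation, "residues", annotation)
        keys = {r.key for r in residues}
        labels = np.array([r.key in keys for r in self.residues], dtype=int)
        return replace(self, labels=labels)


@dataclass
class MetaModelConfig:
    max_depth: int = 4
    alpha: float = 0.0          # L1 pruning/regularization on leaf weights
    n_trees: int = 200
    learning_rate: float = 0.1
    seed: int = 42

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


# default tuning grid for max_depth x alpha
DEFAULT_GRID = {"max_depth": [3, 4, 5], "alpha": [0.0, 0.5, 1.0]}


@dataclass
class FoldSplit:
    """One held-out test set plus training folds (antigen-id lists)."""

    test: list[str]
    train_folds: list[list[str]]

    @property
    def all_train(self) -> list[str]:
        return [a for fold in self.train_folds for a in fold]

    def cv_rounds(self):
        """Yield (train_ids, validation_ids) leaving one training fold out."""
        for i, fold in enumerate(self.train_folds):
            train = [a for j, f in enumerate(self.train_folds) if j != i for a in f]
            yield train, list(fold)


@dataclass
class MetaModel:
    model: XGBClassifier
    feature_names: list[str]
    config: MetaModelConfig
    training_antigens: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "MetaModel":
        obj = joblib.load(Path(path))
        if not isinstance(obj, MetaModel):
            raise TypeError(f"{path} does not contain a MetaModel")
        return obj


def load_scores(
    paths: dict[str, str | Path],
    structure: AntigenStructure,
    antigen_id: str = "antigen",
) -> ScoreTable:
    """Assemble per-classifier score files into one table.

    Rows follow the structure's residue order; classifier column order follows
    the input order.  Residues missing from a score file are imputed to 0
    (no interface evidence) with a warning; a file sharing no residues with
    the structure is an error.
    """
    columns: dict[str, np.ndarray] = {}
    for name, path in paths.items():
        scored = io.read_score_file(path)
        hits = [r.key in scored for r in structure.residues]
        if not any(hits):
            raise ValueError(
                f"score file {path} has no residues in common with the structure")
        values = np.zeros(len(structure))
        for i, rid in enumerate(structure.residues):
            if hits[i]:
                values[i] = scored[rid.key]
            else:
                warnings.warn(f"{name}: no score for residue {rid}; imputed 0")
        columns[name] = values
    return ScoreTable(antigen_id, list(structure.residues), pd.DataFrame(columns))


def normalize_scores(table: ScoreTable) -> ScoreTable:
    """Min-max rescale each classifier column to [0,1] within this antigen.

    Base classifiers report on query-dependent scales; per-antigen rescaling
    makes tracks comparable across antigens.  A constant column carries no
    ranking information and maps to all zeros (with a warning).  Idempotent.
    """
    out = table.scores.copy()
    for name in out.columns:
        col = out[name].to_numpy(dtype=float)
        lo, hi = col.min(), col.max()
        if hi > lo:
            out[name] = (col - lo) / (hi - lo)
        else:
            warnings.warn(f"classifier {name!r} is constant on "
                          f"{table.antigen_id}; normalized to zeros")
            out[name] = np.zeros_like(col)
    return replace(table, scores=out)


def make_folds(
    sizes: dict[str, int],
    n_folds: int = 3,
    seed: int = 42,
    test_size: int | None = None,
) -> FoldSplit:
    """Partition antigens into one test set plus ``n_folds`` training sets.

    Antigens are stratified by size tertile so every fold sees a similar size
    distribution (each fold's tertile counts are within one antigen of the
    proportional share).  Fold sizes are as equal as possible unless
    ``test_size`` pins the held-out set (useful to reproduce a fixed
    benchmark partition); the remainder is then split equally among the training folds.
    Deterministic under a fixed seed.
    """
    ids = list(sizes)
    n = len(ids)
    n_groups = n_folds + 1
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} antigens, got {n}")

    quotas = np.full(n_groups, n // n_groups, dtype=int)
    quotas[: n % n_groups] += 1
    if test_size is not None:
        if not 0 < test_size <= n - n_folds:
            raise ValueError("test_size leaves too few antigens for training")
        rest = n - test_size
        quotas = np.concatenate([[test_size],
                                 np.full(n_folds, rest // n_folds, dtype=int)])
        quotas[1: 1 + rest % n_folds] += 1

    rng = np.random.default_rng(seed)
    by_size = sorted(ids, key=lambda a: (sizes[a], a))
    strata = np.array_split(np.array(by_size, dtype=object), 3)

    groups: list[list[str]] = [[] for _ in range(n_groups)]
    remaining = quotas.copy()
    for s, stratum in enumerate(strata):
        stratum = list(stratum)
        rng.shuffle(stratum)
        order = [(s + j) % n_groups for j in range(n_groups)]
        cursor = 0
        for aid in stratum:
            while remaining[order[cursor % n_groups]] == 0:
                cursor += 1
            groups[order[cursor % n_groups]].append(aid)
            remaining[order[cursor % n_groups]] -= 1
            cursor += 1
    return FoldSplit(test=groups[0], train_folds=groups[1:])


def _stack(tables: list[ScoreTable]):
    features = tables[0].classifiers
    for t in tables:
        if t.classifiers != features:
            raise ValueError("inconsistent classifier columns across tables")
        if t.labels is None:
            raise ValueError(f"table {t.antigen_id} has no labels")
    X = np.vstack([t.scores.to_numpy(dtype=float) for t in tables])
    y = np.concatenate([t.labels for t in tables])
    return X, y, features


def train_meta(
    tables: ScoreTable | list[ScoreTable],
    config: MetaModelConfig | None = None,
) -> MetaModel:
    """Fit the gradient-boosted tree meta-classifier on labelled score tables.

    Class imbalance (epitopal residues are rare) is handled through
    ``scale_pos_weight`` = #negatives/#positives on the training data.
    Training is bitwise-reproducible under a fixed config seed.
    """
    if isinstance(tables, ScoreTable):
        tables = [tables]
    config = config or MetaModelConfig()
    X, y, features = _stack(tables)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("training labels contain a single class")
    clf = XGBClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        reg_alpha=config.alpha,
        random_state=config.seed,
        scale_pos_weight=(len(y) - n_pos) / n_pos,
        tree_method="hist",
        n_jobs=1,
        eval_metric="logloss",
    )
    clf.fit(X, y)
    return MetaModel(clf, features, config, [t.antigen_id for t in tables])


def predict_meta(model: MetaModel, table: ScoreTable) -> np.ndarray:
    """Consensus interface-likelihood score in [0,1] per residue."""
    if table.classifiers != model.feature_names:
        raise ValueError(
            f"feature mismatch: model has {model.feature_names}, "
            f"table has {table.classifiers}")
    return model.model.predict_proba(table.scores.to_numpy(dtype=float))[:, 1]


def tune_meta(
    tables_by_antigen: dict[str, ScoreTable],
    split: FoldSplit,
    grid: dict[str, list] | None = None,
    base_config: MetaModelConfig | None = None,
) -> tuple[MetaModel, pd.DataFrame]:
    """Inner-CV grid search over (max_depth, alpha) on the training folds.

    Each grid point is scored by mean ROC-AUC over the leave-one-training-
    fold-out rounds; the best config (ties -> first in grid order) is refit on
    all training antigens.  Returns the refit model and the grid results.
    """
    grid = grid or DEFAULT_GRID
    base = base_config or MetaModelConfig()
    records = []
    best = None
    for depth, alpha in product(grid["max_depth"], grid["alpha"]):
        config = replace(base, max_depth=depth, alpha=alpha)
        aucs = []
        for train_ids, val_ids in split.cv_rounds():
            model = train_meta([tables_by_antigen[a] for a in train_ids], config)
            val = [tables_by_antigen[a] for a in val_ids]
            scores = np.concatenate([predict_meta(model, t) for t in val])
            labels = np.concatenate([t.labels for t in val])
            if labels.min() == labels.max():
                continue
            aucs.append(roc_auc_score(labels, scores))
        mean_auc = float(np.mean(aucs)) if aucs else float("nan")
        records.append({"max_depth": depth, "alpha": alpha, "cv_roc_auc": mean_auc})
        if best is None or mean_auc > best[0]:
            best = (mean_auc, config)
    final = train_meta([tables_by_antigen[a] for a in split.all_train], best[1])
    return final, pd.DataFrame(records)
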