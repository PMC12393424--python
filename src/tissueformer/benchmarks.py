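"""Comparator methods: single-cell classifiers and group-feature pipelines.

Group-level baselines compress a cell group into a fixed feature vector —
either the pseudobulk (mean) expression or a normalized cell-type
histogram — and classify it with logistic regression or a random forest.
Single-cell heuristics predict a cell's area from its type alone (modal
lookup) or from its nearest same-type neighbors in expression space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .data import CellTable, ValidationError
from .grouping import CellGroup

logger = logging.getLogger(__name__)


@dataclass
class GroupFeatureMatrix:
    """Feature rows per group plus their labels."""

    features: np.ndarray
    kind: str  # "pseudobulk" | "type_histogram"
    labels: np.ndarray

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.kind == "type_histogram":
            if (self.features < 0).any() or not np.allclose(
                self.features.sum(axis=1), 1.0
            ):
                raise ValidationError("type histograms must be normalized")


@dataclass
class LogZTransform:
    """log(1+x) then per-feature z-score, with moments fit on training rows."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "LogZTransform":
        lx = np.log1p(x)
        std = lx.std(axis=0, ddof=0)
        return cls(mean=lx.mean(axis=0), std=np.where(std > 0, std, 1.0))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return (np.log1p(x) - self.mean) / self.std


def pseudobulk_features(
    groups: Sequence[CellGroup],
    table: CellTable,
    transform: LogZTransform | None = None,
    fit_transform: bool = True,
    apply_transform: bool = True,
) -> tuple[GroupFeatureMatrix, LogZTransform | None]:
    """Mean member counts per group, then log1p + z-scoring.

    The z-score moments are fit on the given rows when ``fit_transform``
    (training data); pass the fitted ``transform`` for held-out rows.
    ``apply_transform=False`` returns the raw per-group mean counts.
    """
    if any(g.size == 0 for g in groups):
        raise ValidationError("empty group")
    counts = table.counts_dense()
    raw = np.stack([counts[g.member_indices].mean(axis=0) for g in groups])
    labels = np.asarray([g.label for g in groups])
    if not apply_transform:
        return GroupFeatureMatrix(raw, "pseudobulk", labels), None
    if transform is None:
        if not fit_transform:
            raise ValidationError("need a fitted transform for held-out features")
        transform = LogZTransform.fit(raw)
    feats = transform(raw)
    return GroupFeatureMatrix(feats, "pseudobulk", labels), transform


def type_composition_features(
    groups: Sequence[CellGroup],
    table: CellTable,
    level: str = "h3",
) -> GroupFeatureMatrix:
    """Normalized histogram over the full cell-type alphabet per group."""
    if level not in ("h2", "h3"):
        raise ValidationError(f"unknown type level {level!r}")
    col = table.type_h3 if level == "h3" else table.type_h2
    if col is None:
        raise ValidationError(f"table has no {level} type labels")
    codes = np.asarray(col.codes)
    if (codes < 0).any():
        raise ValidationError("some cells have missing type labels")
    n_types = len(col.categories)
    feats = np.zeros((len(groups), n_types))
    for i, g in enumerate(groups):
        c = np.bincount(codes[g.member_indices], minlength=n_types)
        feats[i] = c / c.sum()
    labels = np.asarray([g.label for g in groups])
    return GroupFeatureMatrix(feats, "type_histogram", labels)


def fit_feature_classifier(
    features: GroupFeatureMatrix,
    algorithm: str = "logistic",
    rng_seed: int = 0,
    **hyperparams,
):
    """Fit the standard comparator on group features.

    Defaults: logistic regression with the lbfgs solver and no
    regularization; random forest with 200 trees, depth 15, 33% of
    features per split, min samples 5 per split and 2 per leaf.
    """
    labels = features.labels.astype(str)
    if len(np.unique(labels)) < 2:
        raise ValidationError("training rows contain a single class")
    if algorithm == "logistic":
        params = dict(solver="lbfgs", penalty=None, max_iter=2000)
        params.update(hyperparams)
        clf = LogisticRegression(**params)
    elif algorithm == "random_forest":
        params = dict(
            n_estimators=200,
            max_depth=15,
            max_features=0.33,
            min_samples_split=5,
            min_samples_leaf=2,
            random_state=rng_seed,
        )
        params.update(hyperparams)
        clf = RandomForestClassifier(**params)
    else:
        raise ValidationError(f"unknown algorithm {algorithm!r}")
    clf.fit(features.features, labels)
    return clf


def cell_type_modal_predict(
    train_table: CellTable,
    test_table: CellTable,
    level: str = "h3",
) -> np.ndarray:
    """Predict each test cell's area as the modal area of its type in training.

    Types unseen in training fall back to the global modal area.
    """
    col_tr = train_table.type_h3 if level == "h3" else train_table.type_h2
    col_te = test_table.type_h3 if level == "h3" else test_table.type_h2
    if col_tr is None or col_te is None:
        raise ValidationError(f"both tables need {level} type labels")
    if train_table.area_label is None:
        raise ValidationError("training cells need area labels")
    areas = np.asarray(train_table.area_label).astype(str)
    types_tr = np.asarray(col_tr).astype(str)
    types_te = np.asarray(col_te)
    if any(t is None or t != t for t in types_te):
        raise ValidationError("untyped test cell")
    global_modal = _modal(areas)
    table_map = {
        t: _modal(areas[types_tr == t]) for t in np.unique(types_tr)
    }
    return np.array([table_map.get(str(t), global_modal) for t in types_te])


def _modal(values: np.ndarray) -> str:
    uniq, counts = np.unique(values, return_counts=True)
    return uniq[np.argmax(counts)]


def cell_type_kneighbors_predict(
    train_table: CellTable,
    test_table: CellTable,
    k: int = 5,
    level: str = "h3",
    metric_space: str = "expression",
) -> np.ndarray:
    """Modal area of the k nearest same-type training cells.

    Neighbors are found in log1p/z-scored expression space by default
    (spatial neighbors would leak the label through geometry; a config
    switch retains the alternative).
    """
    col_tr = train_table.type_h3 if level == "h3" else train_table.type_h2
    col_te = test_table.type_h3 if level == "h3" else test_table.type_h2
    if col_tr is None or col_te is None:
        raise ValidationError(f"both tables need {level} type labels")
    areas = np.asarray(train_table.area_label).astype(str)
    types_tr = np.asarray(col_tr).astype(str)
    types_te = np.asarray(col_te).astype(str)
    if metric_space == "expression":
        tf = LogZTransform.fit(train_table.counts_dense())
        x_tr = tf(train_table.counts_dense())
        x_te = tf(test_table.counts_dense())
    elif metric_space == "spatial":
        x_tr, x_te = train_table.xy, test_table.xy
    else:
        raise ValidationError(f"unknown metric space {metric_space!r}")

    preds = np.empty(len(types_te), dtype=object)
    for t in np.unique(types_te):
        sel_te = types_te == t
        sel_tr = types_tr == t
        if sel_tr.sum() == 0:
            preds[sel_te] = _modal(areas)
            warnings.warn(f"type {t!r} unseen in training; using global modal area")
            continue
        kk = min(k, int(sel_tr.sum()))
        if kk < k:
            warnings.warn(f"type {t!r} has only {kk} training cells (< k={k})")
        pool = x_tr[sel_tr]
        pool_areas = areas[sel_tr]
        q = x_te[sel_te]
        d2 = ((q[:, None, :] - pool[None, :, :]) ** 2).sum(axis=2)
        nn_idx = np.argpartition(d2, kk - 1, axis=1)[:, :kk]
        preds[sel_te] = [_modal(pool_areas[row]) for row in nn_idx]
    return preds.astype(str)
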