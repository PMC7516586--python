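"""Feature vectors from multilevel maps and leave-one-session-out kNN.

Each map segment at the finest selected level defines one *class* — the task
is to recognise which time window of the post-stimulus second a sample came
from, i.e. which eye-movement event it contains.  A feature specification
picks 1-3 contiguous map levels (named by their segment lengths, e.g.
``set64_128_256``) and one or all three measures; for class ``c`` the feature
vector holds the normalized cell ``(l_X, c)`` at the finest selected level
``l_X`` plus that segment's ancestor cells at each coarser selected level,
for every selected measure.  The class count is
``Ncl = NEMr / (Nss * 2**(l_X - 1))`` (16, 8, 4 or 2 at the defaults).

Classification is kNN (Euclidean distance, uniform majority vote) under
leave-one-group-out cross-validation, where a group is one
participant-session: all recordings of a session are held out together, so
accuracies measure generalisation to unseen sessions.  Vote ties are broken
deterministically by the smaller summed neighbour distance (so that on
uninformative features no class index is systematically favoured), with the
lowest class index as the final fallback for exact distance ties.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.neighbors import NearestNeighbors

from .measures import ParameterError
from .mlmap import MEASURES, MapCollection, segment_bounds

logger = logging.getLogger("emmap.classify")

__all__ = [
    "FeatureSpec",
    "LabeledFeatures",
    "ClassificationReport",
    "SpecError",
    "CVError",
    "class_count",
    "assemble_features",
    "knn_loso_cv",
    "accuracy_table",
]


class SpecError(ValueError):
    """Invalid feature specification."""


class CVError(ValueError):
    """Cross-validation cannot be set up (e.g. a single group)."""


def class_count(lx: int, nemr: int = 1024, nss: int = 64) -> int:
    """Number of classes when the finest selected map level is ``lx``.

    ``Ncl = NEMr / (Nss * 2**(lx - 1))``: 16, 8, 4, 2 for lx = 1..4 at the
    default 1024/64 geometry.
    """
    if lx < 1:
        raise SpecError(f"level must be >= 1, got {lx}")
    denom = nss * 2 ** (lx - 1)
    if nemr % denom != 0:
        raise SpecError(f"nemr={nemr} not divisible by nss*2^(lx-1)={denom}")
    return nemr // denom


@dataclass(frozen=True)
class FeatureSpec:
    """Which map levels x measures form the feature vector.

    ``levels`` must be a contiguous run of 1-3 levels from {1..4};
    ``measures`` a non-empty subset of (ApEn, FuzEn, LLE).  The spec's name
    follows the ``set64_128_256_ApEn_FuzEn_LLE`` convention (levels named by
    segment length in ms).
    """

    levels: tuple[int, ...]
    measures: tuple[str, ...] = MEASURES

    def __post_init__(self) -> None:
        levels = tuple(self.levels)
        if not 1 <= len(levels) <= 3:
            raise SpecError(f"need 1-3 levels, got {levels}")
        if sorted(levels) != list(range(min(levels), min(levels) + len(levels))):
            raise SpecError(f"levels must be contiguous, got {levels}")
        if any(l < 1 or l > 4 for l in levels):
            raise SpecError(f"levels must lie in 1..4, got {levels}")
        measures = tuple(self.measures)
        if not measures or any(m not in MEASURES for m in measures):
            raise SpecError(f"measures must be a non-empty subset of {MEASURES}")
        object.__setattr__(self, "levels", tuple(sorted(levels)))
        object.__setattr__(self, "measures", measures)

    @property
    def lx(self) -> int:
        """Finest (lowest) selected level; defines the class segmentation."""
        return min(self.levels)

    @property
    def n_features(self) -> int:
        return len(self.levels) * len(self.measures)

    def n_classes(self, nemr: int = 1024, nss: int = 64) -> int:
        return class_count(self.lx, nemr, nss)

    def name(self, nss: int = 64) -> str:
        sizes = "_".join(str(nss * 2 ** (l - 1)) for l in self.levels)
        return f"set{sizes}_" + "_".join(self.measures)

    @classmethod
    def from_name(cls, name: str, nss: int = 64) -> "FeatureSpec":
        """Parse e.g. ``set64_128_ApEn`` or ``set128_256_512_ApEn_FuzEn_LLE``."""
        match = re.fullmatch(r"set((?:\d+_)*\d+)((?:_(?:ApEn|FuzEn|LLE))+)", name)
        if not match:
            raise SpecError(f"cannot parse feature-set name {name!r}")
        sizes = [int(s) for s in match.group(1).split("_")]
        levels = []
        for size in sizes:
            if size % nss != 0 or (size // nss) & (size // nss - 1):
                raise SpecError(f"segment size {size} is not nss*2^k for nss={nss}")
            levels.append(int(np.log2(size // nss)) + 1)
        measures = tuple(match.group(2).strip("_").split("_"))
        return cls(levels=tuple(levels), measures=measures)


@dataclass
class LabeledFeatures:
    """Sample matrix with class labels and CV group ids.

    One row per (series, class); ``y`` holds 1-based class indices,
    ``groups`` the participant-session identifier of the source series.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    series_ids: np.ndarray
    spec: FeatureSpec
    nss: int = 64
    nemr: int = 1024
    n_dropped: int = 0

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes(self.nemr, self.nss)

    def feature_names(self) -> list[str]:
        return [
            f"{measure}_L{level}"
            for measure in self.spec.measures
            for level in self.spec.levels
        ]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names())
        df.insert(0, "series_id", self.series_ids)
        df.insert(1, "group", self.groups)
        df.insert(2, "label", self.y)
        return df


@dataclass
class ClassificationReport:
    """Pooled leave-one-group-out results for one feature set and k."""

    spec_name: str
    k: int
    classes: np.ndarray
    per_class_accuracy: np.ndarray
    confusion: np.ndarray  # rows: true class, cols: predicted
    n_folds: int
    fold_averaged: bool = False
    nss: int = 64
    nemr: int = 1024

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def segment_label(self, cls: int) -> str:
        lx = int(np.log2(self.nemr // (self.nss * len(self.classes)))) + 1
        start, end = segment_bounds(lx, cls, self.nss, self.nemr)
        return f"{start}-{end}"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spec": self.spec_name,
                "k": self.k,
                "segment": [self.segment_label(c) for c in self.classes],
                "class": self.classes,
                "accuracy": self.per_class_accuracy,
                "n_test": self.confusion.sum(axis=1),
            }
        )


def _knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, k: int, n_cls: int
) -> np.ndarray:
    """Majority-vote kNN with deterministic tie-breaking.

    Among vote-tied classes, the one whose tied neighbours are closer
    (smaller summed distance) wins; exact distance ties fall back to the
    lowest class index.
    """
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(X_train)
    dist, idx = nn.kneighbors(X_test)
    labels = y_train[idx]  # (n_test, k)
    pred = np.empty(X_test.shape[0], dtype=int)
    for i in range(X_test.shape[0]):
        votes = np.bincount(labels[i], minlength=n_cls + 1)
        best = votes.max()
        tied = np.flatnonzero(votes == best)
        if tied.size == 1:
            pred[i] = tied[0]
            continue
        sums = np.array([dist[i][labels[i] == c].sum() for c in tied])
        pred[i] = tied[np.flatnonzero(sums == sums.min()).min()]
    return pred


def _ancestor_index(cls: int, lx: int, level: int) -> int:
    """1-based index at ``level`` >= ``lx`` of the cell containing class ``cls``."""
    return (cls - 1) // 2 ** (level - lx) + 1


def assemble_features(collection: MapCollection, spec: FeatureSpec) -> LabeledFeatures:
    """Build the labelled sample matrix for one feature specification.

    Requires a normalized collection (values in [0, 1]).  Each series
    contributes one row per class; rows containing any missing feature are
    dropped (count logged and recorded).
    """
    if collection.normalized is None:
        raise SpecError("collection must be normalized before feature assembly")
    nemr, nss = collection.nemr, collection.nss
    n_cls = spec.n_classes(nemr, nss)
    if max(spec.levels) > collection.maps[next(iter(collection.maps))][0].n_levels - 1:
        raise SpecError(f"levels {spec.levels} exceed the map's feature levels")
    for measure in spec.measures:
        if measure not in collection.normalized:
            raise SpecError(f"collection has no {measure} maps")

    rows, labels, groups, sids = [], [], [], []
    dropped = 0
    n_series = len(collection.series_meta)
    for i in range(n_series):
        sid = collection.series_meta["series_id"].iloc[i]
        group = collection.series_meta["group"].iloc[i]
        for cls in range(1, n_cls + 1):
            feats = [
                collection.normalized[measure][i].cell(level, _ancestor_index(cls, spec.lx, level))
                for measure in spec.measures
                for level in spec.levels
            ]
            if not all(np.isfinite(feats)):
                dropped += 1
                continue
            rows.append(feats)
            labels.append(cls)
            groups.append(group)
            sids.append(sid)
    if dropped:
        logger.warning("dropped %d feature rows with missing cells (%s)", dropped, spec.name(nss))
    X = np.asarray(rows, dtype=float) if rows else np.empty((0, spec.n_features))
    return LabeledFeatures(
        X=X, y=np.asarray(labels, dtype=int), groups=np.asarray(groups),
        series_ids=np.asarray(sids), spec=spec, nss=nss, nemr=nemr, n_dropped=dropped,
    )


def knn_loso_cv(
    data: LabeledFeatures,
    k: int,
    fold_safe_normalization: bool = False,
    fold_averaged: bool = False,
) -> ClassificationReport:
    """Leave-one-group-out kNN classification of map segments.

    One fold per participant-session group; Euclidean kNN with uniform
    majority vote (vote ties resolved by smaller summed neighbour distance,
    then lowest class index).  Per-class accuracy is pooled over folds by
    default; ``fold_averaged=True`` averages per-fold accuracies instead.
    ``fold_safe_normalization`` re-fits a min-max rescaling per feature on
    each training fold (the leakage-free alternative to the dataset-wide
    normalization).
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    unique_groups = np.unique(data.groups)
    if unique_groups.size < 2:
        raise CVError("need at least 2 participant-session groups for leave-one-out CV")
    n_cls = data.n_classes
    classes = np.arange(1, n_cls + 1)
    confusion = np.zeros((n_cls, n_cls), dtype=int)
    fold_acc: list[np.ndarray] = []
    splitter = LeaveOneGroupOut()
    for train_idx, test_idx in splitter.split(data.X, data.y, data.groups):
        if k >= train_idx.size:
            raise ParameterError(
                f"k={k} must be smaller than the training-set size {train_idx.size}"
            )
        X_train, X_test = data.X[train_idx], data.X[test_idx]
        if fold_safe_normalization:
            lo = X_train.min(axis=0)
            span = X_train.max(axis=0) - lo
            span[span == 0] = 1.0
            X_train = (X_train - lo) / span
            X_test = (X_test - lo) / span
        pred = _knn_predict(X_train, data.y[train_idx], X_test, k, n_cls)
        fold_conf = np.zeros((n_cls, n_cls), dtype=int)
        for true, hat in zip(data.y[test_idx], pred):
            fold_conf[true - 1, hat - 1] += 1
        confusion += fold_conf
        with np.errstate(invalid="ignore", divide="ignore"):
            fold_acc.append(np.diag(fold_conf) / fold_conf.sum(axis=1))
    if fold_averaged:
        per_class = np.nanmean(np.vstack(fold_acc), axis=0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            per_class = np.diag(confusion) / confusion.sum(axis=1)
    return ClassificationReport(
        spec_name=data.spec.name(data.nss), k=k, classes=classes,
        per_class_accuracy=per_class, confusion=confusion,
        n_folds=unique_groups.size, fold_averaged=fold_averaged,
        nss=data.nss, nemr=data.nemr,
    )


def accuracy_table(
    reports: Sequence[ClassificationReport],
    specs: Sequence[FeatureSpec] | None = None,
    first_n_segments: int = 4,
) -> pd.DataFrame:
    """Per-segment accuracies, one column per feature set (report tables' shape).

    Rows are the first ``first_n_segments`` classes in time order (the later
    segments all sit inside the fixation and are reported only on request);
    pass ``first_n_segments=None`` for the full table.
    """
    if not reports:
        raise SpecError("no reports to tabulate")
    if specs is not None:
        if len(specs) != len(reports):
            raise SpecError("specs and reports are misaligned")
        for spec, report in zip(specs, reports):
            if spec.name(report.nss) != report.spec_name:
                raise SpecError(
                    f"report {report.spec_name} does not match spec {spec.name(report.nss)}"
                )
    columns = {}
    index = None
    for report in reports:
        limit = len(report.classes) if first_n_segments is None else first_n_segments
        limit = min(limit, len(report.classes))
        labels = [report.segment_label(c) for c in report.classes[:limit]]
        col = pd.Series(report.per_class_accuracy[:limit], index=labels)
        columns[f"{report.spec_name}_k{report.k}"] = col
        if index is None or len(labels) > len(index):
            index = labels
    table = pd.DataFrame(columns)
    table.index.name = "segment"
    return table
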