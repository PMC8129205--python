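"""Anatomical-domain demarcation from domain-labeled tracer pixels.

Segmented tracer-signal coordinates, each inheriting the domain label of the
section it came from (medial / lateral / caudal), train an ensemble of
RBF-kernel soft-margin SVMs — one member per (C, gamma) pair on power-of-two
grids, 64 members by default.  Each member is scored by its mean accuracy
over repeated stratified cross-validation and the ensemble labels a query
point by an accuracy-weighted vote.  Dense classification of every pixel in
a nucleus mask then yields the domain boundary map for that atlas level;
boundaries are computed independently per level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

CLASS_ORDER = ("medial", "lateral", "caudal")

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-2, 6))  # 2^-2 .. 2^5
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-5, 3))  # 2^-5 .. 2^2


@dataclass
class LabeledPoints:
    """Per-atlas-level 2D coordinates with domain labels."""

    level_id: str
    points: np.ndarray  # (n, 2) pixel coordinates
    labels: np.ndarray  # (n,) strings drawn from CLASS_ORDER

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels must have equal length")
        unknown = set(self.labels) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown domain labels: {sorted(unknown)}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.level_id,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "label": self.labels,
            }
        )


@dataclass
class SvmMember:
    C: float
    gamma: float
    classifier: SVC
    accuracy: float  # mean cross-validated accuracy a_i


@dataclass
class SvmEnsemble:
    """Accuracy-weighted ensemble of RBF SVMs for one atlas level."""

    level_id: str
    members: list[SvmMember]
    classes: tuple[str, ...]
    scale_mean: np.ndarray
    scale_std: np.ndarray

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([m.accuracy for m in self.members])

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "C": [m.C for m in self.members],
                "gamma": [m.gamma for m in self.members],
                "accuracy": [m.accuracy for m in self.members],
            }
        )


@dataclass
class BoundaryMap:
    """Dense per-pixel domain labeling over a nucleus mask."""

    level_id: str
    raster: np.ndarray  # (H, W) int: class index into CLASS_ORDER, -1 outside
    mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.raster.shape != self.mask.shape:
            raise ValueError("raster and mask shapes differ")
        if np.any(self.raster[self.mask] < 0):
            raise ValueError("every mask pixel must be labeled")

    def domain_pixel_counts(self) -> dict[str, int]:
        vals = self.raster[self.mask]
        return {
            cls: int(np.sum(vals == k)) for k, cls in enumerate(CLASS_ORDER)
        }


def build_training_set(sections: list[LabeledPoints]) -> LabeledPoints:
    """Pool segmented label coordinates of all sections at one atlas level.

    Duplicates are retained: each foreground pixel is one training sample.
    """
    if not sections:
        raise ValueError("need at least one section")
    levels = {s.level_id for s in sections}
    if len(levels) > 1:
        raise ValueError(f"sections span multiple levels: {sorted(levels)}")
    return LabeledPoints(
        level_id=sections[0].level_id,
        points=np.concatenate([s.points for s in sections]),
        labels=np.concatenate([s.labels for s in sections]),
    )


def train_ensemble(
    data: LabeledPoints,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    cv_folds: int = 3,
    cv_repeats: int = 10,
    seed: int = 0,
) -> SvmEnsemble:
    """Train one SVM per (C, gamma) pair and score it by cross-validation.

    Coordinates are z-scored per level before the RBF kernel so the gamma
    grid has a scale-free meaning.  Each member's accuracy a_i is the mean
    over ``cv_repeats`` independent repeats of stratified ``cv_folds``-fold
    cross-validation; members are refit on the full data afterwards.
    """
    labels, counts = np.unique(data.labels.astype(str), return_counts=True)
    if len(labels) < 2:
        raise ValueError("training data must contain at least 2 classes")
    thin = labels[counts < cv_folds]
    if len(thin):
        raise ValueError(
            f"classes with fewer than {cv_folds} points: {thin.tolist()}"
        )

    mean = data.points.mean(axis=0)
    std = data.points.std(axis=0)
    std[std == 0] = 1.0
    X = (data.points - mean) / std
    y = data.labels.astype(str)

    cv = RepeatedStratifiedKFold(
        n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed
    )
    folds = [(tr, te) for tr, te in cv.split(X, y)]

    members = []
    for C, gamma in itertools.product(c_grid, gamma_grid):
        accs = []
        for tr, te in folds:
            clf = SVC(C=C, gamma=gamma, kernel="rbf", cache_size=256)
            clf.fit(X[tr], y[tr])
            accs.append(clf.score(X[te], y[te]))
        final = SVC(C=C, gamma=gamma, kernel="rbf", cache_size=256)
        final.fit(X, y)
        members.append(
            SvmMember(
                C=float(C),
                gamma=float(gamma),
                classifier=final,
                accuracy=float(np.mean(accs)),
            )
        )

    present = tuple(c for c in CLASS_ORDER if c in set(y))
    return SvmEnsemble(
        level_id=data.level_id,
        members=members,
        classes=present,
        scale_mean=mean,
        scale_std=std,
    )


def ensemble_predict(model: SvmEnsemble, points: np.ndarray) -> np.ndarray:
    """Accuracy-weighted vote over ensemble members.

    Each point receives the label maximizing the accuracy-weighted count of
    members predicting it; ties break by the fixed class order
    medial < lateral < caudal.
    """
    if not model.members:
        raise ValueError("untrained ensemble")
    pts = np.asarray(points, dtype=float)
    X = (pts - model.scale_mean) / model.scale_std
    scores = np.zeros((len(X), len(CLASS_ORDER)))
    class_idx = {c: k for k, c in enumerate(CLASS_ORDER)}
    for m in model.members:
        pred = m.classifier.predict(X)
        for cls, k in class_idx.items():
            scores[:, k] += m.accuracy * (pred == cls)
    # argmax with ties resolved to the lowest class index
    winners = np.argmax(scores, axis=1)
    return np.array([CLASS_ORDER[k] for k in winners], dtype=object)


def demarcate(model: SvmEnsemble, mask: np.ndarray) -> BoundaryMap:
    """Dense classification of every pixel inside a nucleus mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    labels = ensemble_predict(model, pts)
    class_idx = {c: k for k, c in enumerate(CLASS_ORDER)}
    raster = np.full(mask.shape, -1, dtype=np.int8)
    raster[ys, xs] = [class_idx[c] for c in labels]
    return BoundaryMap(level_id=model.level_id, raster=raster, mask=mask)


@dataclass
class AgreementReport:
    fraction: float
    confusion: pd.DataFrame  # rows = reference, cols = auto
    per_domain_dice: dict[str, float] = field(default_factory=dict)


def agreement(auto: BoundaryMap, reference: BoundaryMap) -> AgreementReport:
    """Pixelwise agreement between two domain maps over a shared mask."""
    if auto.level_id != reference.level_id:
        raise ValueError("boundary maps are from different levels")
    if auto.mask.shape != reference.mask.shape or not np.array_equal(
        auto.mask, reference.mask
    ):
        raise ValueError("boundary maps have different masks")
    a = auto.raster[auto.mask]
    r = reference.raster[reference.mask]
    frac = float(np.mean(a == r))
    k = len(CLASS_ORDER)
    conf = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            conf[i, j] = int(np.sum((r == i) & (a == j)))
    confusion = pd.DataFrame(conf, index=CLASS_ORDER, columns=CLASS_ORDER)
    dice = {}
    for i, cls in enumerate(CLASS_ORDER):
        denom = int(np.sum(a == i) + np.sum(r == i))
        if denom:
            dice[cls] = 2.0 * np.sum((a == i) & (r == i)) / denom
    return AgreementReport(fraction=frac, confusion=confusion, per_domain_dice=dice)
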