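"""Supervised attribution of change objects and accuracy assessment.

Objects are labelled fire / harvest / road / condition with a random
forest over their spectral and geometric metrics.  Accuracy is reported
the way burned-area products report it: a reference-by-predicted
confusion matrix with per-class omission (1 - recall) and commission
(1 - precision) errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .config import CLASS_ORDER
from .objects import ChangeObject
from .synth import TruthLedger

FEATURES = (
    "delta_nbr", "delta_tcb", "delta_tcg", "delta_tcw",
    "pre_nbr", "post_nbr", "pre_tcb", "post_tcb",
    "pre_tcg", "post_tcg", "pre_tcw", "post_tcw",
    "area_ha", "perimeter_m", "compactness", "fractal_dimension",
)


@dataclass
class AttributionModel:
    classifier: RandomForestClassifier
    features: tuple[str, ...]
    classes: tuple[str, ...]
    training_size: int
    seed: int


@dataclass
class AttributionResult:
    object_ids: np.ndarray
    predicted: np.ndarray  # class names
    scores: np.ndarray  # (n, n_classes) rows sum to 1, columns = classes
    classes: tuple[str, ...]
    model: AttributionModel


@dataclass
class AccuracyReport:
    """Confusion matrix (reference rows x predicted columns) and rates."""

    matrix: pd.DataFrame
    overall_accuracy: float
    omission: pd.Series  # per class; NaN = not applicable
    commission: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.matrix.copy()
        out["omission"] = self.omission
        out.loc["commission"] = list(self.commission) + [np.nan]
        return out


def feature_matrix(objects: list[ChangeObject],
                   features=FEATURES) -> np.ndarray:
    X = np.empty((len(objects), len(features)))
    for i, o in enumerate(objects):
        for j, f in enumerate(features):
            v = o.spectral.get(f, getattr(o, f, None))
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValueError(
                    f"object {o.object_id} is missing feature {f!r}")
            X[i, j] = v
    return X


def match_truth(objects: list[ChangeObject], truth: TruthLedger,
                year_tolerance: int = 1) -> list[str | None]:
    """Label objects by majority truth class among member pixels.

    A pixel matches a truth event when the detected change year is within
    ``year_tolerance`` of the event year.  Objects with no matching pixel
    get ``None`` (spurious detections).
    """
    stacks = {cls: truth.class_mask_stack(cls) for cls in CLASS_ORDER}
    y0 = int(truth.years[0])
    n_years = len(truth.years)
    labels = []
    for o in objects:
        yi = o.change_year - y0
        lo, hi = max(0, yi - year_tolerance), min(n_years, yi + year_tolerance + 1)
        votes = {}
        for cls in CLASS_ORDER:
            window = stacks[cls][lo:hi, o.pixels[:, 0], o.pixels[:, 1]]
            votes[cls] = int(window.any(axis=0).sum())
        best = max(CLASS_ORDER, key=lambda c: votes[c])
        labels.append(best if votes[best] > 0 else None)
    return labels


def sample_reference(labels: list[str], centroids: np.ndarray,
                     extent: tuple[int, int], n_per_class: int,
                     spatial_bins: int = 9, seed: int = 0) -> np.ndarray:
    """Class-stratified, spatially spread evaluation sample.

    The extent is tiled into roughly ``spatial_bins`` rectangular bins and
    at most ``ceil(n_per_class / spatial_bins)`` objects of a class are
    taken per bin; if the caps leave a class short, remaining objects of
    that class are topped up regardless of bin.  Returns object indices.
    Raises if a requested class has no objects at all.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    b_r = max(1, int(math.floor(math.sqrt(spatial_bins))))
    b_c = max(1, int(math.ceil(spatial_bins / b_r)))
    n_bins = b_r * b_c
    cap = math.ceil(n_per_class / n_bins)
    bin_r = np.minimum((centroids[:, 0] * b_r / extent[0]).astype(int), b_r - 1)
    bin_c = np.minimum((centroids[:, 1] * b_c / extent[1]).astype(int), b_c - 1)
    bin_id = bin_r * b_c + bin_c

    chosen = []
    for cls in CLASS_ORDER:
        cls_idx = np.flatnonzero(labels == cls)
        if len(cls_idx) == 0:
            raise ValueError(f"no objects available for class {cls!r}")
        picked = []
        for b in range(n_bins):
            pool = cls_idx[bin_id[cls_idx] == b]
            take = min(cap, len(pool), n_per_class - len(picked))
            if take > 0:
                picked.extend(rng.choice(pool, size=take, replace=False))
        if len(picked) < n_per_class:  # top-up ignoring bin caps
            rest = np.setdiff1d(cls_idx, picked)
            extra = min(n_per_class - len(picked), len(rest))
            if extra > 0:
                picked.extend(rng.choice(rest, size=extra, replace=False))
        chosen.extend(picked)
    return np.array(sorted(chosen), dtype=int)


def train_attribution(objects: list[ChangeObject], labels: list[str],
                      features=FEATURES, seed: int = 0,
                      n_trees: int = 500) -> AttributionModel:
    """Train the random-forest attribution model (deterministic per seed)."""
    present = tuple(c for c in CLASS_ORDER if c in set(labels))
    if len(present) < 2:
        raise ValueError("training set must contain at least 2 classes")
    X = feature_matrix(objects, features)
    y = np.asarray(labels, dtype=object)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(X, y)
    return AttributionModel(classifier=clf, features=tuple(features),
                            classes=present, training_size=len(objects),
                            seed=seed)


def predict_from_scores(scores: np.ndarray, classes) -> np.ndarray:
    """Argmax over class scores; ties go to the first class in
    fire < harvest < road < condition order."""
    classes = list(classes)
    order = [classes.index(c) for c in CLASS_ORDER if c in classes]
    ordered = np.asarray(scores)[:, order]
    names = [classes[j] for j in order]
    return np.array([names[i] for i in np.argmax(ordered, axis=1)],
                    dtype=object)


def classify_objects(model: AttributionModel,
                     objects: list[ChangeObject]) -> AttributionResult:
    """Label every object; ties in score go to the first class in
    fire < harvest < road < condition order."""
    X = feature_matrix(objects, model.features)
    raw = model.classifier.predict_proba(X)
    # reorder columns into canonical class order
    cols = list(model.classifier.classes_)
    classes = tuple(c for c in CLASS_ORDER if c in cols)
    scores = np.column_stack([raw[:, cols.index(c)] for c in classes])
    scores = scores / scores.sum(axis=1, keepdims=True)
    predicted = predict_from_scores(scores, classes)
    for o, p in zip(objects, predicted):
        o.label = str(p)
    return AttributionResult(
        object_ids=np.array([o.object_id for o in objects]),
        predicted=predicted, scores=scores, classes=classes, model=model,
    )


def assess_accuracy(predicted, reference,
                    classes=CLASS_ORDER) -> AccuracyReport:
    """Confusion matrix, overall accuracy, omission and commission errors.

    Omission(c) = 1 - recall(c); commission(c) = 1 - precision(c); both
    are NaN (not applicable) when the corresponding marginal is zero.
    """
    predicted = np.asarray(predicted, dtype=object)
    reference = np.asarray(reference, dtype=object)
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference lengths differ")
    classes = [c for c in classes]
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for ref, pred in zip(reference, predicted):
        mat.loc[ref, pred] += 1
    total = mat.values.sum()
    diag = np.diag(mat.values).astype(float)
    row_sums = mat.sum(axis=1).to_numpy().astype(float)
    col_sums = mat.sum(axis=0).to_numpy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        omission = 1.0 - np.where(row_sums > 0, diag / row_sums, np.nan)
        commission = 1.0 - np.where(col_sums > 0, diag / col_sums, np.nan)
    return AccuracyReport(
        matrix=mat,
        overall_accuracy=float(diag.sum() / total) if total else np.nan,
        omission=pd.Series(omission, index=classes),
        commission=pd.Series(commission, index=classes),
    )
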