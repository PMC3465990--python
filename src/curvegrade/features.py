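"""Six-feature assembly and two-stage SVM severity grading.

The feature vector per patient (image pair) is:

    F1  total exudate area (px, color image)
    F2  microaneurysm count inside the FAZ boundary
    F3  total microaneurysm count
    F4  vessel area (px)
    F5  FAZ area (px)
    F6  variance of FAZ boundary-to-centroid distances (px^2)

Grading is a cascade of two soft-margin RBF support-vector machines on
standardized features: stage 1 separates grade 1 (no retinopathy) from
grades 2+3; stage 2, consulted only when stage 1 rejects grade 1,
separates grade 2 (mild/moderate) from grade 3 (severe/proliferative).
The evaluation protocol mirrors a stratified 30% train / 70% test split
repeated over reshuffles with one-vs-rest sensitivity/specificity per
grade, macro-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exudates import ExudateResult
from .faz import FazResult
from .microaneurysms import MaResult

__all__ = [
    "FeatureVector",
    "CascadeModel",
    "DegenerateTrainingSetError",
    "extract_features",
    "train_cascade",
    "predict_grade",
    "predict_grades",
    "evaluate",
    "repeated_split_protocol",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "area_exudates",
    "mas_in_faz",
    "total_mas",
    "area_vessels",
    "area_faz",
    "faz_distance_variance",
)

GRADE_LABELS = {1: "no DR", 2: "mild/moderate NPDR", 3: "severe NPDR/PDR"}


class DegenerateTrainingSetError(ValueError):
    """Training data does not contain all three grades."""


@dataclass(frozen=True)
class FeatureVector:
    area_exudates: float
    mas_in_faz: int
    total_mas: int
    area_vessels: float
    area_faz: float
    faz_distance_variance: float

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "FeatureVector":
        arr = np.asarray(arr, dtype=float)
        return cls(
            area_exudates=float(arr[0]),
            mas_in_faz=int(round(arr[1])),
            total_mas=int(round(arr[2])),
            area_vessels=float(arr[3]),
            area_faz=float(arr[4]),
            faz_distance_variance=float(arr[5]),
        )


def extract_features(
    ex: ExudateResult,
    ma: MaResult,
    vessel_mask: np.ndarray,
    faz: FazResult,
) -> FeatureVector:
    """Assemble the six-feature vector from the per-modality stage results."""
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    for other in (ex.mask, ma.mask, faz.mask):
        if other.shape != vessel_mask.shape:
            raise ValueError("stage results come from differently shaped images")
    return FeatureVector(
        area_exudates=float(ex.total_area),
        mas_in_faz=int(ma.count_in_faz),
        total_mas=int(ma.total_count),
        area_vessels=float(vessel_mask.sum()),
        area_faz=float(faz.area),
        faz_distance_variance=float(faz.distance_variance),
    )


def _to_matrix(features: Iterable) -> np.ndarray:
    rows = []
    for f in features:
        rows.append(f.as_array() if isinstance(f, FeatureVector) else np.asarray(f, dtype=float))
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[1] != 6:
        raise ValueError("expected an (n, 6) feature matrix")
    return X


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise distance of the (standardized)
    training points: gamma = 1 / (2 * median^2)."""
    n = X.shape[0]
    if n < 2:
        return 1.0
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = np.sqrt(np.median(d2[np.triu_indices(n, k=1)]))
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


@dataclass
class CascadeModel:
    """Two-stage SVM cascade with a shared feature scaler."""

    scaler: StandardScaler
    stage1: SVC  # grade 1 vs {2, 3}
    stage2: SVC  # grade 2 vs 3
    gamma: float = field(default=1.0)


def train_cascade(
    features: Iterable,
    labels: Sequence[int],
    seed: int = 0,
    C: float = 10.0,
) -> CascadeModel:
    """Train the cascade on (features, grade labels in {1, 2, 3}).

    Both stages share one standardizer fit on the full training set; the
    RBF width comes from the median heuristic on the standardized features.
    Deterministic given the seed.
    """
    X = _to_matrix(features)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels differ in length")
    present = set(np.unique(y))
    if present != {1, 2, 3}:
        raise DegenerateTrainingSetError(
            f"training set must contain grades 1, 2 and 3; got {sorted(present)}"
        )
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    gamma = _median_heuristic_gamma(Z)
    rng_state = int(seed) % (2**31)
    stage1 = SVC(C=C, kernel="rbf", gamma=gamma, random_state=rng_state)
    stage1.fit(Z, (y == 1).astype(int))
    second = y != 1
    stage2 = SVC(C=C, kernel="rbf", gamma=gamma, random_state=rng_state)
    stage2.fit(Z[second], (y[second] == 2).astype(int))
    return CascadeModel(scaler=scaler, stage1=stage1, stage2=stage2, gamma=gamma)


def predict_grades(model: CascadeModel, features: Iterable) -> np.ndarray:
    """Vectorized cascade prediction: stage 1 first, stage 2 only for
    samples stage 1 rejects as grade 1."""
    X = _to_matrix(features)
    Z = model.scaler.transform(X)
    out = np.empty(X.shape[0], dtype=int)
    is1 = model.stage1.predict(Z).astype(bool)
    out[is1] = 1
    if (~is1).any():
        is2 = model.stage2.predict(Z[~is1]).astype(bool)
        out[~is1] = np.where(is2, 2, 3)
    return out


def predict_grade(model: CascadeModel, fv) -> int:
    """Grade a single feature vector (1, 2 or 3)."""
    return int(predict_grades(model, [fv])[0])


def evaluate(model: CascadeModel, features: Iterable, labels: Sequence[int]) -> Dict:
    """One-vs-rest sensitivity and specificity per grade, plus macro means."""
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty evaluation set")
    pred = predict_grades(model, features)
    per_grade = {}
    sens, spec = [], []
    for g in (1, 2, 3):
        tp = int(np.sum((pred == g) & (y == g)))
        fn = int(np.sum((pred != g) & (y == g)))
        tn = int(np.sum((pred != g) & (y != g)))
        fp = int(np.sum((pred == g) & (y != g)))
        se = tp / (tp + fn) if tp + fn else float("nan")
        sp = tn / (tn + fp) if tn + fp else float("nan")
        per_grade[g] = {"sensitivity": se, "specificity": sp}
        if not np.isnan(se):
            sens.append(se)
        if not np.isnan(sp):
            spec.append(sp)
    return {
        "per_grade": per_grade,
        "macro_sensitivity": float(np.mean(sens)) if sens else float("nan"),
        "macro_specificity": float(np.mean(spec)) if spec else float("nan"),
        "accuracy": float(np.mean(pred == y)),
    }


def repeated_split_protocol(
    features: Iterable,
    labels: Sequence[int],
    train_frac: float = 0.3,
    n_repeats: int = 10,
    seed: int = 0,
    C: float = 10.0,
) -> Dict:
    """Stratified repeated split-and-average evaluation.

    Trains on a stratified ``train_frac`` of the cohort and evaluates on the
    rest, ``n_repeats`` times with reshuffled splits; sensitivities and
    specificities are averaged over repeats.
    """
    X = _to_matrix(features)
    y = np.asarray(labels, dtype=int)
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_frac, random_state=int(seed) % (2**31)
    )
    sens, spec, acc = [], [], []
    for train_idx, test_idx in splitter.split(X, y):
        model = train_cascade(X[train_idx], y[train_idx], seed=seed, C=C)
        rep = evaluate(model, X[test_idx], y[test_idx])
        sens.append(rep["macro_sensitivity"])
        spec.append(rep["macro_specificity"])
        acc.append(rep["accuracy"])
    return {
        "mean_sensitivity": float(np.mean(sens)),
        "mean_specificity": float(np.mean(spec)),
        "mean_accuracy": float(np.mean(acc)),
        "n_repeats": n_repeats,
        "train_frac": train_frac,
        "per_repeat_sensitivity": [float(s) for s in sens],
        "per_repeat_specificity": [float(s) for s in spec],
    }
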