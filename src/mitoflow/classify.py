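"""Morphology and health classifiers, area fractions, feature-subset search.

Morphology classification is per-object (punctate / networked / swollen);
health classification is per-video (control / treated) on per-video mean
features.  Four algorithms are exposed: k-nearest neighbours, Gaussian
naive Bayes, linear discriminant analysis (pooled covariance) and an
error-correcting output-code classifier built from one-vs-one linear
discriminants with Hamming-style vote decoding.

Deterministic conventions: features are z-scored by training statistics for
knn / discriminant / ecoc (naive Bayes is scale-equivariant and left
unscaled); vote and posterior ties resolve to the smallest class index in
sorted label order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsOneClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .io import logger

ALGORITHMS = ("knn", "naive_bayes", "discriminant", "ecoc")


@dataclass
class TrainingLibrary:
    """Labelled feature vectors with per-record provenance.

    ``X`` is ``(n, d)``; ``feature_names`` names the columns; ``y`` holds
    class labels; ``provenance`` identifies the source of each record so
    train/test splits can be made disjoint by origin.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n, d) with one label per row")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match X columns")
        if np.unique(self.y).size < 2:
            raise ValueError("training library needs at least 2 classes")
        if not np.isfinite(self.X).all():
            raise ValueError("missing or non-finite feature values")
        if self.provenance is None:
            self.provenance = np.arange(self.X.shape[0])
        else:
            self.provenance = np.asarray(self.provenance)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def select(self, names: Sequence[str]) -> "TrainingLibrary":
        idx = [self.feature_names.index(n) for n in names]
        return TrainingLibrary(
            X=self.X[:, idx], y=self.y, feature_names=list(names), provenance=self.provenance
        )

    @classmethod
    def from_csv(cls, path: str | Path, label_column: str = "label") -> "TrainingLibrary":
        """Load a library from one CSV with a label column, or a directory of
        per-class CSVs named ``<class>.csv``."""
        path = Path(path)
        if path.is_dir():
            frames = []
            for f in sorted(path.glob("*.csv")):
                df = pd.read_csv(f)
                df[label_column] = f.stem
                frames.append(df)
            if not frames:
                raise ValueError(f"no CSV files in {path}")
            df = pd.concat(frames, ignore_index=True)
        else:
            df = pd.read_csv(path)
        feature_cols = [
            c for c in df.columns if c not in (label_column, "frame", "provenance")
        ]
        prov = df["provenance"].to_numpy() if "provenance" in df else None
        return cls(
            X=df[feature_cols].to_numpy(float),
            y=df[label_column].to_numpy(),
            feature_names=feature_cols,
            provenance=prov,
        )


@dataclass
class ClassifierSpec:
    """Algorithm choice and its hyper-parameters."""

    algorithm: str = "knn"
    k: int = 5
    feature_subset: Sequence[str] = ()
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class Model:
    """A trained classifier plus the preprocessing statistics it needs."""

    spec: ClassifierSpec
    estimator: object
    classes: np.ndarray
    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    training_accuracy: float = 0.0
    _train_X: np.ndarray | None = None
    _train_y: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.scale


def _make_estimator(spec: ClassifierSpec):
    if spec.algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k)
    if spec.algorithm == "naive_bayes":
        return GaussianNB()
    if spec.algorithm == "discriminant":
        return LinearDiscriminantAnalysis()
    # one-vs-one is the minimal complete output code for 2-3 classes;
    # vote decoding is Hamming decoding of that code
    return OneVsOneClassifier(LinearDiscriminantAnalysis())


def train(library: TrainingLibrary, spec: ClassifierSpec) -> Model:
    """Fit a classifier on a training library.

    Features are restricted to ``spec.feature_subset`` when given and
    z-scored by training statistics unless the algorithm is naive Bayes or
    ``spec.standardize`` is off.  Gaussian fits require >= 2 records per
    class.  The returned model records its training-set accuracy.
    """
    lib = library.select(list(spec.feature_subset)) if spec.feature_subset else library
    if spec.algorithm in ("naive_bayes", "discriminant", "ecoc"):
        counts = pd.Series(lib.y).value_counts()
        if (counts < 2).any():
            raise ValueError("each class needs >= 2 records for Gaussian fits")
    use_std = spec.standardize and spec.algorithm != "naive_bayes"
    if use_std:
        mean = lib.X.mean(axis=0)
        scale = lib.X.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
    else:
        mean = np.zeros(lib.X.shape[1])
        scale = np.ones(lib.X.shape[1])
    Xs = (lib.X - mean) / scale
    est = _make_estimator(spec)
    est.fit(Xs, lib.y)
    acc = float(np.mean(est.predict(Xs) == lib.y)) * 100.0
    model = Model(
        spec=spec,
        estimator=est,
        classes=np.unique(lib.y),
        feature_names=lib.feature_names,
        mean=mean,
        scale=scale,
        training_accuracy=acc,
        _train_X=lib.X,
        _train_y=lib.y,
    )
    logger.debug("trained %s on %d records, training accuracy %.2f%%",
                 spec.algorithm, lib.X.shape[0], acc)
    return model


def predict_morphology(model: Model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict one label per object plus per-class scores.

    Scores are posterior probabilities (or vote fractions for the
    one-vs-one code); columns follow ``model.classes``.  Predictions are
    deterministic given the model.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected (n, {len(model.feature_names)}) features, got {X.shape}"
        )
    if not np.isfinite(X).all():
        raise ValueError("missing feature values")
    Xs = model.transform(X)
    labels = model.estimator.predict(Xs)
    if hasattr(model.estimator, "predict_proba"):
        scores = model.estimator.predict_proba(Xs)
    else:
        decision = model.estimator.decision_function(Xs)
        if decision.ndim == 1:
            decision = np.stack([-decision, decision], axis=1)
        e = np.exp(decision - decision.max(axis=1, keepdims=True))
        scores = e / e.sum(axis=1, keepdims=True)
    return labels, scores


def evaluate(model: Model, library: TrainingLibrary) -> tuple[float, pd.DataFrame]:
    """Accuracy (%) and confusion table on a held-out library."""
    if library.X.shape[0] == 0:
        raise ValueError("empty test set")
    lib = library.select(model.feature_names) if library.feature_names != model.feature_names else library
    pred, _ = predict_morphology(model, lib.X)
    acc = float(np.mean(pred == lib.y)) * 100.0
    classes = sorted(set(model.classes) | set(lib.y))
    table = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(lib.y, pred):
        table.loc[t, p] += 1
    return acc, table


# ---------------------------------------------------------------------------
# Class area fractions
# ---------------------------------------------------------------------------

def class_area_fractions(
    areas: Sequence[float] | np.ndarray, classes: Sequence[str]
) -> dict[str, float]:
    """Per-class area fraction of the total mitochondrial area in one cell.

    ``fraction_c = sum(area of class-c objects) / sum(area of all objects)``;
    the fractions sum to 1.
    """
    areas = np.asarray(areas, float)
    if len(areas) != len(classes):
        raise ValueError("one class per object required")
    total = areas.sum()
    if total <= 0:
        raise ValueError("cell has zero mitochondrial area")
    out: dict[str, float] = {}
    for a, c in zip(areas, classes):
        out[c] = out.get(c, 0.0) + float(a)
    return {c: v / total for c, v in out.items()}


def group_class_fractions(per_cell: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Mean class fraction across cells (absent classes count as 0)."""
    classes = sorted({c for cell in per_cell for c in cell})
    return {c: float(np.mean([cell.get(c, 0.0) for cell in per_cell])) for c in classes}


# ---------------------------------------------------------------------------
# Health classification (per-video)
# ---------------------------------------------------------------------------

def video_health_classify(
    library: TrainingLibrary,
    spec: ClassifierSpec,
    n_folds: int = 5,
) -> tuple[Model, float, list[float]]:
    """Stratified k-fold cross-validated accuracy on per-video features.

    Returns the model refit on all videos, the mean CV accuracy (%), and
    the per-fold accuracies.  Folds are shuffled deterministically from
    ``spec.seed``.
    """
    counts = pd.Series(library.y).value_counts()
    if counts.size < 2:
        raise ValueError("health classification needs two arms")
    if (counts < 4).any():
        raise ValueError("need >= 4 videos per arm for cross-validation")
    n_folds = min(n_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    lib = library.select(list(spec.feature_subset)) if spec.feature_subset else library
    fold_acc: list[float] = []
    for train_idx, test_idx in skf.split(lib.X, lib.y):
        sub_spec = ClassifierSpec(
            algorithm=spec.algorithm, k=spec.k, feature_subset=(),
            standardize=spec.standardize, seed=spec.seed,
        )
        m = train(
            TrainingLibrary(lib.X[train_idx], lib.y[train_idx], lib.feature_names,
                            lib.provenance[train_idx]),
            sub_spec,
        )
        acc, _ = evaluate(
            m,
            TrainingLibrary(lib.X[test_idx], lib.y[test_idx], lib.feature_names,
                            lib.provenance[test_idx]),
        )
        fold_acc.append(acc)
    model = train(lib, ClassifierSpec(algorithm=spec.algorithm, k=spec.k, feature_subset=(),
                                      standardize=spec.standardize, seed=spec.seed))
    return model, float(np.mean(fold_acc)), fold_acc


# ---------------------------------------------------------------------------
# Exhaustive feature-subset search
# ---------------------------------------------------------------------------

def exhaustive_feature_search(
    library: TrainingLibrary,
    specs: Sequence[ClassifierSpec],
    max_subset_size: int = 5,
    test_library: TrainingLibrary | None = None,
    n_folds: int = 5,
    max_evaluations: int = 200_000,
) -> pd.DataFrame:
    """Evaluate every feature subset of size <= ``max_subset_size``.

    With a held-out ``test_library``, each subset/algorithm pair is trained
    on the library and scored on the test set (the single-split protocol);
    otherwise stratified ``n_folds`` cross-validation on the library is
    used.  Results are sorted by accuracy (descending), then subset size,
    then lexicographic subset order, so ranking is deterministic.
    """
    names = library.feature_names
    n_subsets = sum(
        1 for size in range(1, min(max_subset_size, len(names)) + 1)
        for _ in itertools.combinations(names, size)
    )
    if n_subsets * len(specs) > max_evaluations:
        raise ValueError(
            f"{n_subsets * len(specs)} evaluations exceed the cap {max_evaluations}"
        )
    rows = []
    for size in range(1, min(max_subset_size, len(names)) + 1):
        for subset in itertools.combinations(names, size):
            for spec in specs:
                sub_spec = ClassifierSpec(
                    algorithm=spec.algorithm, k=spec.k, feature_subset=subset,
                    standardize=spec.standardize, seed=spec.seed,
                )
                if test_library is not None:
                    model = train(library, sub_spec)
                    acc, _ = evaluate(model, test_library.select(list(subset)))
                else:
                    _, acc, _ = video_health_classify(library, sub_spec, n_folds=n_folds)
                rows.append(
                    {
                        "subset": ",".join(subset),
                        "size": size,
                        "algorithm": spec.algorithm,
                        "accuracy": acc,
                    }
                )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["accuracy", "size", "subset"], ascending=[False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model serialisation
# ---------------------------------------------------------------------------

def save_model(model: Model, path: str | Path) -> None:
    """Serialise a model as JSON: spec + training data.

    Loading retrains deterministically from the stored records, so the JSON
    is a complete, human-inspectable description of the classifier.
    """
    payload = {
        "spec": {
            "algorithm": model.spec.algorithm,
            "k": model.spec.k,
            "feature_subset": list(model.spec.feature_subset),
            "standardize": model.spec.standardize,
            "seed": model.spec.seed,
        },
        "feature_names": model.feature_names,
        "train_X": np.asarray(model._train_X).tolist(),
        "train_y": np.asarray(model._train_y).tolist(),
        "training_accuracy": model.training_accuracy,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> Model:
    payload = json.loads(Path(path).read_text())
    spec = ClassifierSpec(**payload["spec"])
    lib = TrainingLibrary(
        X=np.array(payload["train_X"], float),
        y=np.array(payload["train_y"]),
        feature_names=payload["feature_names"],
    )
    # subset was already applied before saving
    spec = ClassifierSpec(
        algorithm=spec.algorithm, k=spec.k, feature_subset=(),
        standardize=spec.standardize, seed=spec.seed,
    )
    return train(lib, spec)
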