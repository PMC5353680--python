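"""Weighted RBF/polynomial kernels and the wrapper cost function.

The weighted kernel with per-dimension scale factors w equals the plain
kernel evaluated on sqrt(w)-scaled inputs, so a standard soft-margin SVM
trained on the rescaled dataset serves as the weighted-kernel machine.
Fitness is mean stratified k-fold cross-validated accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .dataset import Dataset


@dataclass
class KernelSpec:
    """Kernel family and SVM regularization.

    rbf: k(x, z) = exp(-sigma * sum_i w_i (x_i - z_i)^2)
    poly: k(x, z) = (sum_i w_i x_i z_i)^degree
    """

    family: str = "rbf"
    sigma: float = 10.0
    degree: int = 3
    C: float = 100.0

    def __post_init__(self) -> None:
        if self.family not in ("rbf", "poly"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf" and self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.family == "poly" and self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass
class FitnessRecord:
    """Cross-validated accuracy of one candidate subset."""

    bits: tuple
    cv_accuracy: float
    fold_count: int
    evaluation_seed: int
    cached: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.cv_accuracy <= 1.0:
            raise ValueError("cv_accuracy must lie in [0, 1]")


def weighted_kernel_value(x: np.ndarray, z: np.ndarray, w: np.ndarray,
                          spec: KernelSpec) -> float:
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    if not x.shape == z.shape == w.shape:
        raise ValueError("x, z and w must have equal lengths")
    if spec.family == "rbf":
        return float(np.exp(-spec.sigma * np.sum(w * (x - z) ** 2)))
    return float(np.sum(w * x * z) ** spec.degree)


def scale_matrix(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    return X * np.sqrt(w)


def scale_dataset(ds: Dataset, w: np.ndarray) -> Dataset:
    """Multiply each feature column by sqrt(w_i); binary w zeroes deselected
    columns and leaves selected ones untouched."""
    if len(w) != ds.n_features:
        raise ValueError("weight length does not match feature count")
    out = ds.copy()
    out.features = scale_matrix(out.features, w)
    return out


def _make_classifier(spec: KernelSpec, n_classes: int):
    if spec.family == "rbf":
        svc = SVC(C=spec.C, kernel="rbf", gamma=spec.sigma)
    else:
        svc = SVC(C=spec.C, kernel="poly", degree=spec.degree, gamma=1.0, coef0=0.0)
    if n_classes > 2:
        return OneVsRestClassifier(svc)
    return svc


class FitnessEvaluator:
    """Caches fold indices and fitness records for one training dataset.

    The fold partition is drawn once from the evaluation seed and shared by
    every candidate so fitness comparisons are paired. All-zero candidates
    short-circuit to the majority-class rate without training. The cache is
    keyed by the candidate bitstring; ``evaluations`` counts actual
    cross-validation runs (cache hits excluded).
    """

    def __init__(self, ds: Dataset, spec: KernelSpec, folds: int = 5,
                 seed: int = 0) -> None:
        if folds < 2:
            raise ValueError("need at least 2 folds")
        if ds.has_missing():
            raise ValueError("dataset must be preprocessed (no missing entries)")
        self.spec = spec
        self.seed = seed
        self.X = np.ascontiguousarray(ds.features)
        classes, y = np.unique([str(v) for v in ds.labels], return_inverse=True)
        if len(classes) < 2:
            raise ValueError("degenerate labels")
        self.y = y
        self.n_classes = len(classes)
        counts = np.bincount(y)
        self.majority_rate = float(counts.max() / counts.sum())
        min_class = int(counts.min())
        self.folds = min(folds, min_class)
        if self.folds < folds:
            warnings.warn(
                f"reduced folds from {folds} to {self.folds}: smallest class has "
                f"{min_class} instances"
            )
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=seed)
        self.fold_indices = list(skf.split(self.X, self.y))
        self.cache: dict[bytes, FitnessRecord] = {}
        self.evaluations = 0

    def evaluate(self, bits) -> FitnessRecord:
        bits = np.asarray(getattr(bits, "bits", bits), dtype=np.int8)
        if bits.shape != (self.X.shape[1],):
            raise ValueError("candidate length does not match feature count")
        key = bits.tobytes()
        hit = self.cache.get(key)
        if hit is not None:
            return FitnessRecord(hit.bits, hit.cv_accuracy, hit.fold_count,
                                 hit.evaluation_seed, cached=True)
        if not bits.any():
            acc = self.majority_rate
        else:
            cols = np.flatnonzero(bits)
            Xs = self.X[:, cols]
            accs = []
            for tr, te in self.fold_indices:
                clf = _make_classifier(self.spec, self.n_classes)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(Xs[tr], self.y[tr])
                accs.append(float(np.mean(clf.predict(Xs[te]) == self.y[te])))
            acc = float(np.mean(accs))
            self.evaluations += 1
        rec = FitnessRecord(tuple(int(b) for b in bits), acc, self.folds, self.seed)
        self.cache[key] = rec
        return rec


def evaluate_candidate(ds: Dataset, candidate, spec: KernelSpec, folds: int = 5,
                       seed: int = 0, cache: dict | None = None) -> FitnessRecord:
    """One-shot wrapper cost: CV accuracy of the SVM on the rescaled dataset.

    ``cache`` maps (bitstring, seed) to an evaluator so repeated calls with
    the same dataset/seed reuse fold partitions and fitness records.
    """
    key = ("evaluator", seed, folds, id(ds))
    if cache is not None and key in cache:
        ev = cache[key]
    else:
        ev = FitnessEvaluator(ds, spec, folds, seed)
        if cache is not None:
            cache[key] = ev
    return ev.evaluate(candidate)


def holdout_accuracy(train: Dataset, test: Dataset, bits,
                     spec: KernelSpec) -> float:
    """Train on the full training split with the candidate's columns and
    report plain accuracy on the held-out split."""
    bits = np.asarray(getattr(bits, "bits", bits), dtype=np.int8)
    classes, y_tr = np.unique([str(v) for v in train.labels], return_inverse=True)
    lookup = {c: k for k, c in enumerate(classes)}
    y_te = np.array([lookup.get(str(v), -1) for v in test.labels])
    if not bits.any():
        majority = np.bincount(y_tr).argmax()
        return float(np.mean(y_te == majority))
    cols = np.flatnonzero(bits)
    clf = _make_classifier(spec, len(classes))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(train.features[:, cols], y_tr)
    return float(np.mean(clf.predict(test.features[:, cols]) == y_te))
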