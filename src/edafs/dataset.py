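"""Tabular dataset container, loading, preprocessing and splitting.

Feature values are stored as floats with NaN marking missing entries.
Labels are kept verbatim as strings so binary and multiclass problems are
handled uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: cell contents treated as missing when reading tables (UCI dialects)
MISSING_MARKERS = {"", "?", "NA"}


@dataclass
class Dataset:
    """An (m instances x l variables) real-valued classification dataset.

    Parameters
    ----------
    features:
        Float matrix of shape ``(m, l)``; ``NaN`` encodes a missing entry.
    labels:
        One class symbol (string) per instance.
    feature_names:
        ``l`` unique column names.
    class_values:
        Sorted distinct class symbols.
    meta:
        Provenance notes (source path or generator spec, seeds, ground
        truth index sets for synthetic data, ...).
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    class_values: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=object)
        m, l = self.features.shape
        if m < 2:
            raise ValueError("dataset needs at least 2 instances")
        if l < 1:
            raise ValueError("dataset needs at least 1 feature")
        if self.labels.shape != (m,):
            raise ValueError(
                f"label count {self.labels.shape} does not match {m} feature rows"
            )
        self.feature_names = [str(n) for n in self.feature_names]
        if len(self.feature_names) != l:
            raise ValueError("feature_names length does not match feature columns")
        if len(set(self.feature_names)) != l:
            raise ValueError("feature_names must be unique")
        if not self.class_values:
            self.class_values = sorted({str(y) for y in self.labels})

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.features).any())

    def copy(self) -> "Dataset":
        return Dataset(
            self.features.copy(),
            self.labels.copy(),
            list(self.feature_names),
            list(self.class_values),
            dict(self.meta),
        )

    def subset_rows(self, idx: np.ndarray, note: str | None = None) -> "Dataset":
        meta = dict(self.meta)
        if note:
            meta["subset"] = note
        return Dataset(
            self.features[idx],
            self.labels[idx],
            list(self.feature_names),
            list(self.class_values),
            meta,
        )


def _parse_cell(cell: str) -> float:
    s = cell.strip()
    if s in MISSING_MARKERS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        return np.nan


def load_table(path: str, class_column: str | int, delimiter: str = ",") -> Dataset:
    """Read a delimited text table with a header row into a :class:`Dataset`.

    ``class_column`` may be a column name or a positional index. Cells that
    are empty, ``?`` or ``NA``, or that fail to parse as a real number, are
    marked missing.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    if isinstance(class_column, int) and class_column not in df.columns:
        if not -df.shape[1] <= class_column < df.shape[1]:
            raise ValueError(f"class column index {class_column} out of range")
        class_column = df.columns[class_column]
    if class_column not in df.columns:
        raise ValueError(f"class column {class_column!r} not found in header")
    labels = df[class_column].astype(str).str.strip().to_numpy(dtype=object)
    if len(set(labels)) < 2:
        raise ValueError("degenerate labels: class column has fewer than 2 distinct values")
    feat_df = df.drop(columns=[class_column])
    features = np.array(
        [[_parse_cell(c) for c in row] for row in feat_df.itertuples(index=False)],
        dtype=float,
    ).reshape(len(df), feat_df.shape[1])
    return Dataset(
        features,
        labels,
        list(feat_df.columns),
        meta={"source": str(path), "class_column": str(class_column)},
    )


def write_table(ds: Dataset, path: str, class_column: str = "class",
                delimiter: str = ",") -> None:
    """Write a dataset so that :func:`load_table` round-trips it."""
    df = pd.DataFrame(ds.features, columns=ds.feature_names)
    df[class_column] = ds.labels
    df.to_csv(path, sep=delimiter, index=False, na_rep="?")


def _bin_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # right-closed last bin so the maximum falls in bin n_bins-1
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def _fill_mode_mean(col: np.ndarray) -> float:
    observed = col[~np.isnan(col)]
    distinct = np.unique(observed)
    if distinct.size < 10:
        # mode; ties resolved towards the smallest value
        best = max(range(distinct.size),
                   key=lambda k: (np.sum(observed == distinct[k]), -distinct[k]))
        return float(distinct[best])
    return float(observed.mean())


def _naive_bayes_fill(features: np.ndarray, target: int, n_bins: int) -> np.ndarray | None:
    """Predict bin midpoints for the missing entries of column ``target``.

    A small categorical naive Bayes over equal-width binned predictors,
    trained on rows where the target is observed. Returns the fill values
    for the missing rows, or ``None`` when no training rows exist.
    """
    col = features[:, target]
    missing = np.isnan(col)
    train = ~missing
    if not train.any():
        return None
    t_edges = _bin_edges(col[train], n_bins)
    t_bins = _bin_index(col[train], t_edges)
    n_classes = n_bins
    class_counts = np.bincount(t_bins, minlength=n_classes).astype(float)
    log_prior = np.log(class_counts + 1.0)

    predictors = [j for j in range(features.shape[1]) if j != target]
    tables = {}
    for j in predictors:
        pj = features[:, j]
        obs = train & ~np.isnan(pj)
        if not obs.any():
            continue
        edges = _bin_edges(pj[~np.isnan(pj)], n_bins)
        pb = _bin_index(pj[obs], edges)
        tb = t_bins[obs[train]]  # obs is a subset of train rows
        # joint counts: rows = target bin, cols = predictor bin
        joint = np.zeros((n_classes, n_bins))
        np.add.at(joint, (tb, pb), 1.0)
        tables[j] = (edges, np.log(joint + 1.0) - np.log(joint.sum(axis=1, keepdims=True) + n_bins))
    if not tables:
        return None

    mids = 0.5 * (t_edges[:-1] + t_edges[1:])
    fill = np.empty(int(missing.sum()))
    for out_k, row in enumerate(np.flatnonzero(missing)):
        score = log_prior.copy()
        for j, (edges, log_lik) in tables.items():
            v = features[row, j]
            if np.isnan(v):
                continue
            b = int(_bin_index(np.array([v]), edges)[0])
            score += log_lik[:, b]
        fill[out_k] = mids[int(np.argmax(score))]
    return fill


def impute_missing(ds: Dataset, method: str = "naive_bayes", n_bins: int = 5) -> Dataset:
    """Fill missing entries.

    ``naive_bayes`` predicts, for each feature with holes, the equal-width
    bin of the missing value from the other (binned) features and fills with
    the bin midpoint; ``mode_mean`` fills with the per-feature mode when the
    feature has fewer than 10 distinct values, the mean otherwise. Complete
    datasets are returned unchanged (a copy).
    """
    if method not in ("naive_bayes", "mode_mean"):
        raise ValueError(f"unknown imputation method {method!r}")
    out = ds.copy()
    if not out.has_missing():
        return out
    X = out.features
    for j in range(out.n_features):
        col = X[:, j]
        holes = np.isnan(col)
        if not holes.any():
            continue
        if holes.all():
            raise ValueError(f"feature {out.feature_names[j]!r} is missing in every row")
        if method == "mode_mean":
            col[holes] = _fill_mode_mean(col)
        else:
            fill = _naive_bayes_fill(X, j, n_bins)
            if fill is None:
                warnings.warn(
                    f"feature {out.feature_names[j]!r}: no co-observed rows for "
                    "naive Bayes imputation; falling back to mode/mean"
                )
                col[holes] = _fill_mode_mean(col)
            else:
                col[holes] = fill
    out.meta["imputed"] = method
    return out


def normalize_minmax(ds: Dataset) -> Dataset:
    """Map each feature to [0, 1] by (x - min) / (max - min).

    Constant features map to 0 everywhere. Missing entries must have been
    imputed first.
    """
    if ds.has_missing():
        raise ValueError("missing entries present; run impute_missing first")
    out = ds.copy()
    X = out.features
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    constant = span == 0
    span[constant] = 1.0
    out.features = (X - lo) / span
    out.features[:, constant] = 0.0
    out.meta["normalized"] = "minmax"
    return out


def _stratified_train_indices(labels: np.ndarray, n_train: int,
                              rng: np.random.Generator) -> np.ndarray:
    classes = sorted(set(labels))
    per_class = {c: np.flatnonzero(labels == c) for c in classes}
    m = len(labels)
    frac = n_train / m
    base = {c: int(np.floor(frac * len(per_class[c]))) for c in classes}
    short = n_train - sum(base.values())
    # largest fractional remainder first; ties by class order
    remainders = sorted(
        classes, key=lambda c: (-(frac * len(per_class[c]) - base[c]), classes.index(c))
    )
    for c in remainders[:short]:
        base[c] += 1
    picked = []
    for c in classes:
        idx = per_class[c].copy()
        rng.shuffle(idx)
        picked.append(idx[: base[c]])
    return np.sort(np.concatenate(picked))


def split_train_test(ds: Dataset, train_fraction: float, seed: int,
                     stratified: bool = True) -> tuple[Dataset, Dataset]:
    """Disjoint row partition with ``round(train_fraction * m)`` training rows.

    Stratified splits keep per-class proportions within one instance of
    exact proportionality. Equal seeds give identical splits.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly inside (0, 1)")
    m = ds.n_instances
    if m < 4:
        raise ValueError("need at least 4 instances to split")
    labels = np.array([str(y) for y in ds.labels])
    if stratified:
        counts = {c: int(np.sum(labels == c)) for c in set(labels)}
        singletons = [c for c, n in counts.items() if n < 2]
        if singletons:
            raise ValueError(f"stratified split impossible: single-instance classes {singletons}")
    n_train = int(np.floor(train_fraction * m + 0.5))
    rng = np.random.default_rng(seed)
    if stratified:
        train_idx = _stratified_train_indices(labels, n_train, rng)
    else:
        perm = rng.permutation(m)
        train_idx = np.sort(perm[:n_train])
    mask = np.zeros(m, dtype=bool)
    mask[train_idx] = True
    test_idx = np.flatnonzero(~mask)
    return (
        ds.subset_rows(train_idx, note=f"train f={train_fraction} seed={seed}"),
        ds.subset_rows(test_idx, note=f"test f={train_fraction} seed={seed}"),
    )


def shuffle_rows(ds: Dataset, seed: int) -> Dataset:
    """Return a copy with instance order permuted by a seeded generator."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_instances)
    return ds.subset_rows(perm, note=f"shuffled seed={seed}")


def preprocess(ds: Dataset, impute: str = "naive_bayes") -> Dataset:
    """Standard pipeline: impute missing values then min-max normalize."""
    return normalize_minmax(impute_missing(ds, impute))
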