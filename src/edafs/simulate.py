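"""Synthetic case-control generators with pure k-way interactions.

The main generator draws k SNP genotypes in {0,1,2} under Hardy-Weinberg
equilibrium and labels each instance by the parity of the genotype bits
(g mod 2). With allele frequency 0.5 every proper subset of the k relevant
columns carries (in expectation) zero information about the class, while
the full set determines it — the "no lower-order effects" construction.
Irrelevant features are i.i.d. uniform draws appended after the SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import Dataset

CASE, CONTROL = "case", "control"


@dataclass
class EpistasisSpec:
    """Parameters of a parity-epistasis case-control dataset."""

    k: int
    n_noise: int
    m: int
    allele_freq: float = 0.5
    noise_low: float = 0.0
    noise_high: float = 10.0
    leak: float = 0.0  # probability of replacing the label by SNP 0's bit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("interaction order k must be >= 2")
        if self.m < 50:
            raise ValueError("need at least 50 instances")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must lie in (0, 1)")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError("leak must lie in [0, 1]")


def generate_epistasis_dataset(spec: EpistasisSpec) -> Dataset:
    """Generate the k relevant SNP columns and parity labels (no noise yet)."""
    rng = np.random.default_rng(spec.seed)
    genotypes = rng.binomial(2, spec.allele_freq, size=(spec.m, spec.k)).astype(float)
    bits = genotypes.astype(int) % 2
    y = bits.sum(axis=1) % 2
    if spec.leak > 0:
        leaky = rng.random(spec.m) < spec.leak
        y[leaky] = bits[leaky, 0]
    labels = np.where(y == 1, CASE, CONTROL).astype(object)
    ds = Dataset(
        genotypes,
        labels,
        [f"snp_{i}" for i in range(spec.k)],
        class_values=[CASE, CONTROL],
        meta={
            "generator": "parity_epistasis",
            "spec": asdict(spec),
            "relevant": list(range(spec.k)),
            "noisy": [],
        },
    )
    if spec.n_noise:
        ds = add_noise_features(ds, spec.n_noise, spec.noise_low, spec.noise_high,
                                seed=spec.seed + 1)
    return ds


def add_noise_features(ds: Dataset, n_noise: int, low: float = 0.0,
                       high: float = 10.0, seed: int = 0) -> Dataset:
    """Append ``n_noise`` i.i.d. uniform [low, high) columns named noise_0..."""
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    if n_noise == 0:
        return ds.copy()
    if low >= high:
        raise ValueError("noise range requires low < high")
    rng = np.random.default_rng(seed)
    m, l = ds.features.shape
    noise = rng.uniform(low, high, size=(m, n_noise))
    meta = dict(ds.meta)
    meta.setdefault("relevant", list(range(l)))
    meta["noisy"] = list(ds.meta.get("noisy", [])) + list(range(l, l + n_noise))
    meta["noise_range"] = [low, high]
    return Dataset(
        np.hstack([ds.features, noise]),
        ds.labels.copy(),
        list(ds.feature_names) + [f"noise_{i}" for i in range(n_noise)],
        list(ds.class_values),
        meta,
    )


def make_toy_classification(kind: str, m: int, n_noise: int = 0,
                            seed: int = 0) -> Dataset:
    """Small fixtures for kernel and search tests.

    ``xor2``: class is the XOR of two Bernoulli(0.5) features; ``linear``:
    class is the sign of f0 + f1 - 1 on uniform features;
    ``onemax_surrogate``: featureless filler (uniform columns, random
    balanced labels) for optimizer tests driven by a surrogate cost.
    """
    if m < 40:
        raise ValueError("need at least 40 instances")
    rng = np.random.default_rng(seed)
    if kind == "xor2":
        f = rng.integers(0, 2, size=(m, 2)).astype(float)
        y = (f[:, 0].astype(int) ^ f[:, 1].astype(int)) == 1
        relevant = [0, 1]
    elif kind == "linear":
        f = rng.uniform(0, 1, size=(m, 2))
        y = f[:, 0] + f[:, 1] > 1.0
        relevant = [0, 1]
    elif kind == "onemax_surrogate":
        f = rng.uniform(0, 1, size=(m, 2))
        y = np.arange(m) % 2 == 0
        relevant = []
    else:
        raise ValueError(f"unknown toy kind {kind!r}")
    labels = np.where(y, CASE, CONTROL).astype(object)
    ds = Dataset(
        f,
        labels,
        [f"f{i}" for i in range(f.shape[1])],
        class_values=[CASE, CONTROL],
        meta={"generator": kind, "seed": seed, "relevant": relevant, "noisy": []},
    )
    if n_noise:
        ds = add_noise_features(ds, n_noise, 0.0, 1.0, seed=seed + 1)
    return ds


def plugin_mi_bits(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete samples."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((len(xs), len(ys)))
    np.add.at(joint, (xi, yi), 1.0)
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))
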