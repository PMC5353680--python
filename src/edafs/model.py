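"""Bivariate binomial probability model factored over a dependency forest.

Roots carry Bernoulli marginals estimated from bracket counts over the
elite pool; every non-root variable carries a conditional on its parent.
With an empty edge set the model degenerates exactly to independent
per-variable marginals (the univariate variant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dependency import DependencyForest


@dataclass
class Candidate:
    """A binary relevance-indicator vector with an optional fitness."""

    bits: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.ndim != 1 or not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be a flat 0/1 vector")
        if self.fitness is not None and not 0.0 <= self.fitness <= 1.0:
            raise ValueError("fitness must lie in [0, 1]")

    def key(self) -> bytes:
        return self.bits.tobytes()


def _as_pool(pool) -> np.ndarray:
    arr = np.asarray([getattr(c, "bits", c) for c in pool], dtype=int)
    if arr.size == 0:
        raise ValueError("candidate pool is empty")
    return arr


@dataclass
class ForestModel:
    """Counts + structure defining the factored distribution.

    ``rho_i[i, a]`` counts pool members with bit a at position i;
    ``rho_ij[(p, c)][a, b]`` counts members with child bit a and parent
    bit b. Probabilities are derived with ``smoothing`` pseudo-counts so
    they stay strictly inside (0, 1).
    """

    structure: DependencyForest
    rho_i: np.ndarray
    rho_ij: dict[tuple[int, int], np.ndarray]
    pool_size: int
    smoothing: float = 1.0

    @property
    def n_vars(self) -> int:
        return self.structure.n_nodes

    def marginal(self, i: int) -> np.ndarray:
        """Smoothed P(X_i = [0, 1])."""
        s = self.smoothing
        return (self.rho_i[i] + s) / (self.pool_size + 2 * s)

    def marginals(self) -> np.ndarray:
        """Smoothed P(X_i = 1) for every variable."""
        s = self.smoothing
        return (self.rho_i[:, 1] + s) / (self.pool_size + 2 * s)

    def conditional(self, parent: int, child: int) -> np.ndarray:
        """Smoothed 2x2 table P(child = a | parent = b), rows a, columns b."""
        s = self.smoothing
        joint = self.rho_ij[(parent, child)]
        denom = self.rho_i[parent] + 2 * s
        return (joint + s) / denom[np.newaxis, :]

    def sampling_order(self) -> list[int]:
        """Roots first, then children by increasing depth, index ascending."""
        order: list[int] = []
        frontier = sorted(self.structure.roots)
        children: dict[int, list[int]] = {}
        for p, c in self.structure.edges:
            children.setdefault(p, []).append(c)
        while frontier:
            order.extend(frontier)
            frontier = sorted(
                c for p in frontier for c in children.get(p, ())
            )
        return order

    def to_json(self) -> str:
        return json.dumps(
            {
                "structure": self.structure.to_dict(),
                "rho_i": self.rho_i.tolist(),
                "rho_ij": {f"{p},{c}": t.tolist() for (p, c), t in self.rho_ij.items()},
                "pool_size": self.pool_size,
                "smoothing": self.smoothing,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ForestModel":
        d = json.loads(text)
        rho_ij = {}
        for k, t in d["rho_ij"].items():
            p, c = k.split(",")
            rho_ij[(int(p), int(c))] = np.asarray(t, dtype=float)
        return cls(
            structure=DependencyForest.from_dict(d["structure"]),
            rho_i=np.asarray(d["rho_i"], dtype=float),
            rho_ij=rho_ij,
            pool_size=d["pool_size"],
            smoothing=d["smoothing"],
        )


def estimate_model(pool, structure: DependencyForest,
                   smoothing: float = 1.0) -> ForestModel:
    """Frequentist bracket counts over the pool for marginals and edges."""
    arr = _as_pool(pool)
    n, l = arr.shape
    if l != structure.n_nodes:
        raise ValueError(
            f"structure over {structure.n_nodes} variables but candidates have length {l}"
        )
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    rho_i = np.stack([(arr == 0).sum(axis=0), (arr == 1).sum(axis=0)], axis=1).astype(float)
    rho_ij = {}
    for p, c in structure.edges:
        joint = np.zeros((2, 2))
        np.add.at(joint, (arr[:, c], arr[:, p]), 1.0)
        rho_ij[(p, c)] = joint
    return ForestModel(structure, rho_i, rho_ij, pool_size=n, smoothing=smoothing)


def sample_candidates(model: ForestModel, count: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Ancestral sampling: roots from marginals, children from conditionals
    given their sampled parent, in topological order. Returns (count, l) bits."""
    if count < 1:
        raise ValueError("count must be >= 1")
    l = model.n_vars
    out = np.zeros((count, l), dtype=np.int8)
    parent_of = model.structure.parent
    for i in model.sampling_order():
        if i in parent_of:
            p = parent_of[i]
            cond = model.conditional(p, i)  # P(child=a | parent=b)
            p1 = cond[1, out[:, p]]
        else:
            p1 = np.full(count, model.marginal(i)[1])
        out[:, i] = (rng.random(count) < p1).astype(np.int8)
    return out


def candidate_probability(model: ForestModel, candidate) -> float:
    """Exact probability of one bit vector under the factored distribution."""
    bits = np.asarray(getattr(candidate, "bits", candidate), dtype=int)
    if bits.shape != (model.n_vars,):
        raise ValueError("candidate length does not match the model")
    prob = 1.0
    for r in model.structure.roots:
        prob *= model.marginal(r)[bits[r]]
    for p, c in model.structure.edges:
        prob *= model.conditional(p, c)[bits[c], bits[p]]
    return float(prob)
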