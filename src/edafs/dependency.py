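"""Pairwise dependency statistics over a pool of binary candidates and the
spanning-forest dependency structure with minimum-entropy roots."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: 1-df chi-square critical value at alpha = 0.05
CHI2_CRITICAL = 3.84
DEFAULT_MI_TOL = 1e-12

CRITERIA = ("chi2", "mi", "sim", "none")


@dataclass
class PairCounts:
    """Joint counts of the bit values at two candidate positions."""

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        if min(self.n00, self.n01, self.n10, self.n11) < 0:
            raise ValueError("counts must be non-negative")
        if self.N < 1:
            raise ValueError("total count must be >= 1")

    @property
    def N(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    def table(self) -> np.ndarray:
        """2x2 array with rows indexed by the first bit, columns by the second."""
        return np.array([[self.n00, self.n01], [self.n10, self.n11]], dtype=float)


def _as_pool(pool) -> np.ndarray:
    arr = np.asarray([getattr(c, "bits", c) for c in pool], dtype=int)
    if arr.size == 0:
        raise ValueError("candidate pool is empty")
    if arr.ndim != 2:
        raise ValueError("pool must be a list of equal-length bit vectors")
    return arr


def pair_counts(pool, i: int, j: int) -> PairCounts:
    """Exact joint counts of bits at positions ``i`` and ``j`` across the pool."""
    arr = _as_pool(pool)
    if i == j:
        raise ValueError("pair positions must differ")
    bi = arr[:, i]
    bj = arr[:, j]
    return PairCounts(
        n00=int(np.sum((bi == 0) & (bj == 0))),
        n01=int(np.sum((bi == 0) & (bj == 1))),
        n10=int(np.sum((bi == 1) & (bj == 0))),
        n11=int(np.sum((bi == 1) & (bj == 1))),
    )


def chi2_pair(c: PairCounts) -> float:
    """Pearson statistic sum (o-e)^2/e; cells with zero expectation contribute 0."""
    obs = c.table()
    n = obs.sum()
    e = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    mask = e > 0
    return float(np.sum((obs[mask] - e[mask]) ** 2 / e[mask]))


def mi_pair(c: PairCounts) -> float:
    """Plug-in mutual information in bits; 0*log terms vanish."""
    p = c.table() / c.N
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    # clamp: rounding can leave a tiny negative on near-independent tables
    return max(0.0, float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz]))))


def sim_pair(c: PairCounts, alpha: float = 0.05, mi_tol: float = DEFAULT_MI_TOL) -> int:
    """1 iff the chi-square p-value (1 df) is <= alpha AND MI exceeds mi_tol."""
    p_value = stats.chi2.sf(chi2_pair(c), df=1)
    return int(p_value <= alpha and mi_pair(c) > mi_tol)


def marginal_entropy(pool, i: int) -> float:
    """Shannon entropy (bits) of the pool's bit frequency at position ``i``."""
    arr = _as_pool(pool)
    p1 = float(np.mean(arr[:, i]))
    h = 0.0
    for p in (p1, 1.0 - p1):
        if p > 0:
            h -= p * np.log2(p)
    return h


def all_entropies(pool) -> np.ndarray:
    arr = _as_pool(pool)
    p1 = arr.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p1 > 0, p1 * np.log2(p1), 0.0) + np.where(
            p1 < 1, (1 - p1) * np.log2(1 - p1), 0.0
        )
    return -terms


@dataclass
class DependencyStats:
    """Symmetric pairwise statistics over one candidate pool."""

    chi2: np.ndarray
    mi: np.ndarray
    sim: np.ndarray
    entropy: np.ndarray


def compute_stats(pool, alpha: float = 0.05,
                  mi_tol: float = DEFAULT_MI_TOL) -> DependencyStats:
    arr = _as_pool(pool)
    l = arr.shape[1]
    chi2 = np.zeros((l, l))
    mi = np.zeros((l, l))
    sim = np.zeros((l, l), dtype=int)
    for i in range(l):
        for j in range(i + 1, l):
            c = pair_counts(arr, i, j)
            chi2[i, j] = chi2[j, i] = chi2_pair(c)
            mi[i, j] = mi[j, i] = mi_pair(c)
            sim[i, j] = sim[j, i] = sim_pair(c, alpha, mi_tol)
    return DependencyStats(chi2, mi, sim, all_entropies(arr))


def build_edge_set(pool, criterion: str = "sim", alpha: float = 0.05,
                   mi_tol: float = DEFAULT_MI_TOL,
                   chi2_threshold: float = CHI2_CRITICAL) -> list[tuple[int, int, float]]:
    """Candidate edges (i, j, strength) over all unordered pairs.

    chi2 keeps pairs with statistic >= 3.84 (strength = the statistic);
    mi keeps pairs with positive information (strength = MI); sim conjoins
    significance and positive information (strength = MI). ``none`` always
    returns an empty list (univariate degeneration).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion == "none":
        return []
    arr = _as_pool(pool)
    l = arr.shape[1]
    if l < 2:
        raise ValueError("need at least 2 variables")
    edges = []
    for i in range(l):
        for j in range(i + 1, l):
            c = pair_counts(arr, i, j)
            if criterion == "chi2":
                s = chi2_pair(c)
                if s >= chi2_threshold:
                    edges.append((i, j, s))
            elif criterion == "mi":
                s = mi_pair(c)
                if s > mi_tol:
                    edges.append((i, j, s))
            else:  # sim
                if sim_pair(c, alpha, mi_tol):
                    edges.append((i, j, mi_pair(c)))
    return edges


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


@dataclass
class DependencyForest:
    """Directed spanning forest over ``n_nodes`` variables.

    ``parent`` maps every non-root node to its unique parent; ``edges``
    holds (parent, child) pairs oriented away from the roots; ``components``
    partitions all nodes.
    """

    n_nodes: int
    parent: dict[int, int]
    roots: set[int]
    edges: list[tuple[int, int]]
    components: list[list[int]] = field(default_factory=list)

    def undirected_edges(self) -> set[tuple[int, int]]:
        return {(min(a, b), max(a, b)) for a, b in self.edges}

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "parent": {str(k): v for k, v in self.parent.items()},
            "roots": sorted(self.roots),
            "edges": [list(e) for e in self.edges],
            "components": [list(c) for c in self.components],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DependencyForest":
        return cls(
            n_nodes=d["n_nodes"],
            parent={int(k): v for k, v in d["parent"].items()},
            roots=set(d["roots"]),
            edges=[tuple(e) for e in d["edges"]],
            components=[list(c) for c in d["components"]],
        )


def maximum_spanning_edges(edges: list[tuple[int, int, float]],
                           n_nodes: int) -> list[tuple[int, int, float]]:
    """Kruskal scan keeping edges of decreasing strength that join distinct
    trees; ties broken by lexicographic (i, j) so runs are reproducible."""
    uf = _UnionFind(n_nodes)
    kept = []
    for i, j, s in sorted(edges, key=lambda e: (-e[2], e[0], e[1])):
        if uf.union(i, j):
            kept.append((i, j, s))
    return kept


def build_forest(edges: list[tuple[int, int, float]], n_nodes: int,
                 entropies: np.ndarray | None = None,
                 root_rule: str = "min_entropy", seed: int = 0) -> DependencyForest:
    """Maximum-strength spanning forest with per-component roots.

    Roots minimise marginal entropy (ties to the lowest index) or are drawn
    uniformly at random per component when ``root_rule='random'``. Isolated
    nodes become singleton components (and their own roots). Edges are
    oriented away from the roots.
    """
    for i, j, _ in edges:
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise ValueError("edge endpoint out of range")
    if root_rule not in ("min_entropy", "random"):
        raise ValueError(f"unknown root rule {root_rule!r}")
    if root_rule == "min_entropy" and entropies is None:
        raise ValueError("min_entropy root rule requires entropies")

    kept = maximum_spanning_edges(edges, n_nodes)
    adj: dict[int, list[int]] = {v: [] for v in range(n_nodes)}
    uf = _UnionFind(n_nodes)
    for i, j, _ in kept:
        adj[i].append(j)
        adj[j].append(i)
        uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for v in range(n_nodes):
        groups.setdefault(uf.find(v), []).append(v)
    components = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])

    rng = np.random.default_rng(seed)
    roots: set[int] = set()
    for comp in components:
        if len(comp) == 1:
            roots.add(comp[0])
        elif root_rule == "min_entropy":
            roots.add(min(comp, key=lambda v: (entropies[v], v)))
        else:
            roots.add(int(rng.choice(comp)))

    parent: dict[int, int] = {}
    directed: list[tuple[int, int]] = []
    for comp in components:
        root = next(v for v in comp if v in roots)
        frontier = [root]
        seen = {root}
        while frontier:
            nxt = []
            for u in frontier:
                for v in sorted(adj[u]):
                    if v not in seen:
                        seen.add(v)
                        parent[v] = u
                        directed.append((u, v))
                        nxt.append(v)
            frontier = nxt
    return DependencyForest(n_nodes, parent, roots, directed, components)


def stats_to_tsv(matrix: np.ndarray, feature_names: list[str], path: str) -> None:
    """Serialize a symmetric dependency matrix as TSV with name headers."""
    import pandas as pd

    pd.DataFrame(matrix, index=feature_names, columns=feature_names).to_csv(
        path, sep="\t"
    )
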