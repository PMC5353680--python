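"""Multi-repetition protocols: averaging relevance across runs, cutoff
selection, dependency aggregation, Kruskal consensus tree and discovery
scoring."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace, field

import numpy as np

from .dataset import Dataset, shuffle_rows, split_train_test
from .dependency import _UnionFind
from .search import RunResult, SearchConfig, run_search


@dataclass
class DiscoveryScore:
    """(#R, #N): relevant features correctly selected, noisy ones correctly
    excluded."""

    n_relevant_found: int
    n_noise_found: int

    def as_tuple(self) -> tuple[int, int]:
        return (self.n_relevant_found, self.n_noise_found)


@dataclass
class AggregateResult:
    avg_relevance: np.ndarray
    relevant_set: list[int]
    dep_counts: np.ndarray
    consensus: list[tuple[int, int]]
    per_run: list[dict]
    protocol: dict

    def to_dict(self) -> dict:
        return {
            "avg_relevance": self.avg_relevance.tolist(),
            "relevant_set": list(self.relevant_set),
            "dep_counts": self.dep_counts.tolist(),
            "consensus": [list(e) for e in self.consensus],
            "per_run": self.per_run,
            "protocol": self.protocol,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def repeat_protocol(ds: Dataset, cfg: SearchConfig, reps: int, base_seed: int,
                    shuffle: bool = False, train_fraction: float = 0.25,
                    stratified: bool = True, variant: str = "bmda",
                    cost_fn=None) -> list[RunResult]:
    """``reps`` independent runs with derived seeds ``base_seed + r``.

    Each repetition (optionally) shuffles the instance order, splits into
    train/test with its own seed, and runs the search.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    results = []
    for r in range(reps):
        seed = base_seed + r
        dsr = shuffle_rows(ds, seed) if shuffle else ds
        train, test = split_train_test(dsr, train_fraction, seed, stratified)
        results.append(run_search(train, test, replace(cfg, seed=seed),
                                  variant=variant, cost_fn=cost_fn))
    return results


def average_relevance(runs: list[RunResult], accuracy_floor: float = 0.0) -> np.ndarray:
    """Mean of best-candidate bit vectors over runs whose held-out accuracy
    strictly exceeds the floor."""
    passing = [r for r in runs if r.test_accuracy > accuracy_floor]
    if not passing:
        best = max(r.test_accuracy for r in runs) if runs else float("nan")
        raise ValueError(
            f"no run exceeds accuracy floor {accuracy_floor}; best observed {best}"
        )
    return np.mean([np.asarray(r.best.bits, dtype=float) for r in passing], axis=0)


def select_relevant(avg: np.ndarray, cutoff: float) -> list[int]:
    """Indices with averaged relevance strictly greater than the cutoff."""
    avg = np.asarray(avg, dtype=float)
    if (avg < 0).any() or (avg > 1).any():
        raise ValueError("averaged relevance must lie in [0, 1]")
    return [int(i) for i in np.flatnonzero(avg > cutoff)]


def aggregate_dependency_counts(runs: list[RunResult],
                                mode: str = "final_msf") -> np.ndarray:
    """Cross-run dependency occurrence matrix.

    ``final_msf`` counts, per unordered pair, the runs whose final spanning
    forest contains the edge; ``all_iterations`` sums the per-iteration
    inclusion counts of every run.
    """
    if mode not in ("final_msf", "all_iterations"):
        raise ValueError(f"unknown mode {mode!r}")
    if not runs:
        raise ValueError("no runs to aggregate")
    l = len(runs[0].best.bits)
    if any(len(r.best.bits) != l for r in runs):
        raise ValueError("runs disagree on the number of variables")
    counts = np.zeros((l, l), dtype=int)
    for r in runs:
        if mode == "final_msf":
            for a, b in r.final_msf_edges():
                counts[a, b] += 1
                counts[b, a] += 1
        else:
            counts += r.dependency_counts
    return counts


def consensus_tree(counts: np.ndarray) -> list[tuple[int, int]]:
    """Kruskal minimum spanning forest with edge cost 1/count.

    Zero-count pairs are excluded; ties break lexicographically; one tree
    per connected component of the positive-count graph.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    l = counts.shape[0]
    edges = [
        (i, j, int(counts[i, j]))
        for i in range(l) for j in range(i + 1, l) if counts[i, j] > 0
    ]
    if not edges:
        warnings.warn("all dependency counts are zero; consensus tree is empty")
        return []
    uf = _UnionFind(l)
    kept = []
    # cost 1/count: ascending cost == descending count
    for i, j, c in sorted(edges, key=lambda e: (1.0 / e[2], e[0], e[1])):
        if uf.union(i, j):
            kept.append((i, j))
    return sorted(kept)


def discovery_score(selected, truth_relevant, truth_noisy) -> DiscoveryScore:
    """#R = |selected ∩ relevant|; #N = noisy features correctly excluded."""
    selected = set(int(i) for i in selected)
    rel = set(int(i) for i in truth_relevant)
    noisy = set(int(i) for i in truth_noisy)
    if rel & noisy:
        raise ValueError("truth sets overlap")
    return DiscoveryScore(
        n_relevant_found=len(selected & rel),
        n_noise_found=len(noisy - selected),
    )


def bubble_tally(scores: list[DiscoveryScore], max_R: int, max_N: int) -> np.ndarray:
    """(max_R+1) x (max_N+1) count matrix of discovery coordinates."""
    tally = np.zeros((max_R + 1, max_N + 1), dtype=int)
    for s in scores:
        r, n = s.as_tuple()
        if not (0 <= r <= max_R and 0 <= n <= max_N):
            raise ValueError(f"score ({r}, {n}) out of tally range")
        tally[r, n] += 1
    return tally


def aggregate_runs(runs: list[RunResult], accuracy_floor: float = 0.0,
                   cutoff: float = 0.5, dep_mode: str = "final_msf",
                   protocol: dict | None = None) -> AggregateResult:
    """Assemble the full aggregate product from a batch of runs."""
    avg = average_relevance(runs, accuracy_floor)
    dep = aggregate_dependency_counts(runs, dep_mode)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        consensus = consensus_tree(dep) if dep.any() else []
    summaries = [
        {
            "seed": r.seed,
            "best_bits": [int(b) for b in r.best.bits],
            "best_fitness": r.best.fitness,
            "test_accuracy": r.test_accuracy,
            "evaluations": r.evaluations,
            "iterations_run": r.iterations_run,
        }
        for r in runs
    ]
    proto = dict(protocol or {})
    proto.setdefault("reps", len(runs))
    proto.setdefault("accuracy_floor", accuracy_floor)
    proto.setdefault("cutoff", cutoff)
    proto.setdefault("dep_mode", dep_mode)
    return AggregateResult(
        avg_relevance=avg,
        relevant_set=select_relevant(avg, cutoff),
        dep_counts=dep,
        consensus=consensus,
        per_run=summaries,
        protocol=proto,
    )
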