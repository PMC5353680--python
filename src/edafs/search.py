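"""Main evolutionary loop: truncation-elitist sampling over a forest-factored
probability model, guided by the wrapper cost function.

Two variants share the loop: ``bmda`` re-estimates the pairwise dependency
structure every iteration; ``umda`` forces an empty edge set so only the
per-variable marginals evolve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .dataset import Dataset
from .dependency import all_entropies, build_edge_set, build_forest
from .fitness import FitnessEvaluator, KernelSpec, holdout_accuracy
from .model import Candidate, ForestModel, estimate_model, sample_candidates

VARIANTS = ("bmda", "umda")


@dataclass
class SearchConfig:
    """Knobs of one search run."""

    pool_size: int = 20
    max_iters: int = 80
    criterion: str = "sim"
    root_rule: str = "min_entropy"
    elite_fraction: float = 0.5
    convergence_delta: float = 0.01
    smoothing: float = 1.0
    kernel: KernelSpec = field(default_factory=KernelSpec)
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 4 or self.pool_size % 2:
            raise ValueError("pool_size must be even and >= 4")
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must lie in (0, 1)")

    @property
    def elite_size(self) -> int:
        return max(1, int(round(self.pool_size * self.elite_fraction)))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunResult:
    """Everything one search run produced."""

    best: Candidate
    test_accuracy: float
    fitness_trace: list[float]
    final_model: ForestModel
    dependency_counts: np.ndarray
    evaluations: int
    iterations_run: int
    seed: int
    variant: str
    config: dict

    def final_msf_edges(self) -> set[tuple[int, int]]:
        return self.final_model.structure.undirected_edges()

    def to_dict(self) -> dict:
        return {
            "best_bits": [int(b) for b in self.best.bits],
            "best_fitness": self.best.fitness,
            "test_accuracy": self.test_accuracy,
            "fitness_trace": self.fitness_trace,
            "final_model": json.loads(self.final_model.to_json()),
            "dependency_counts": self.dependency_counts.tolist(),
            "evaluations": self.evaluations,
            "iterations_run": self.iterations_run,
            "seed": self.seed,
            "variant": self.variant,
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def has_converged(model: ForestModel, delta: float) -> bool:
    """True iff every marginal probability is within delta of 0 or 1."""
    p = model.marginals()
    return bool(np.all((p <= delta) | (p >= 1.0 - delta)))


class _SurrogateEvaluator:
    """Adapter giving surrogate cost functions the evaluator interface."""

    def __init__(self, cost_fn) -> None:
        self.cost_fn = cost_fn
        self.cache: dict[bytes, float] = {}
        self.evaluations = 0

    def evaluate(self, bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in self.cache:
            self.cache[key] = float(self.cost_fn(bits))
            self.evaluations += 1
        return self.cache[key]


def run_search(train: Dataset, test: Dataset | None, cfg: SearchConfig,
               variant: str = "bmda", cost_fn=None) -> RunResult:
    """Evolve the probability model and return the best candidate found.

    Iteration 0 draws ``pool_size`` candidates from the uniform model; each
    later iteration unions ``pool_size - elite_size`` fresh samples with the
    retained elite, evaluates them, truncates to the elite, and re-estimates
    structure (edges on the elite, forest, minimum-entropy roots) and counts
    from the elite. ``umda`` skips the structure step entirely. Stops at
    ``max_iters`` or when all marginals have saturated.

    ``cost_fn``, when given, replaces the classifier: it maps a bit vector
    to a fitness in [0, 1] (used for optimizer-only tests).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    l = train.n_features
    if test is not None and test.n_features != l:
        raise ValueError("train/test feature counts differ")
    n = cfg.pool_size
    n_elite = cfg.elite_size
    rng = np.random.default_rng(cfg.seed)

    if cost_fn is None:
        evaluator = FitnessEvaluator(train, cfg.kernel, cfg.folds, seed=cfg.seed)
        fitness_of = lambda bits: evaluator.evaluate(bits).cv_accuracy
    else:
        evaluator = _SurrogateEvaluator(cost_fn)
        fitness_of = evaluator.evaluate

    best_bits: np.ndarray | None = None
    best_fitness = -1.0
    trace: list[float] = []
    dep_counts = np.zeros((l, l), dtype=int)
    model: ForestModel | None = None
    elite: np.ndarray | None = None
    elite_fitness: np.ndarray | None = None
    iterations = 0

    for t in range(cfg.max_iters):
        iterations = t + 1
        if t == 0:
            pool = rng.integers(0, 2, size=(n, l), dtype=np.int8)
            fitness = np.array([fitness_of(c) for c in pool])
        else:
            fresh = sample_candidates(model, n - n_elite, rng)
            pool = np.concatenate([fresh, elite])
            fresh_fitness = np.array([fitness_of(c) for c in fresh])
            fitness = np.concatenate([fresh_fitness, elite_fitness])

        order = np.argsort(-fitness, kind="stable")
        top = order[0]
        if fitness[top] > best_fitness:
            best_fitness = float(fitness[top])
            best_bits = pool[top].copy()
        trace.append(best_fitness)

        keep = order[:n_elite]
        elite = pool[keep]
        elite_fitness = fitness[keep]

        if variant == "bmda":
            edges = build_edge_set(elite, cfg.criterion)
        else:
            edges = []
        forest = build_forest(
            edges, l, entropies=all_entropies(elite),
            root_rule=cfg.root_rule, seed=cfg.seed + t + 1,
        )
        model = estimate_model(elite, forest, cfg.smoothing)
        for a, b in forest.undirected_edges():
            dep_counts[a, b] += 1
            dep_counts[b, a] += 1

        if has_converged(model, cfg.convergence_delta):
            break

    if cost_fn is None and test is not None:
        test_acc = holdout_accuracy(train, test, best_bits, cfg.kernel)
    else:
        test_acc = best_fitness

    cfg_dict = cfg.to_dict()
    return RunResult(
        best=Candidate(best_bits, best_fitness),
        test_accuracy=test_acc,
        fitness_trace=trace,
        final_model=model,
        dependency_counts=dep_counts,
        evaluations=evaluator.evaluations,
        iterations_run=iterations,
        seed=cfg.seed,
        variant=variant,
        config=cfg_dict,
    )
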