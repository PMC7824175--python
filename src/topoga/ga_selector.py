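"""Fixed-cardinality genetic algorithm over marker-gene subsets.

A chromosome is an ordered list of n distinct gene indices into the marker
panel.  Each generation crosses randomly chosen parent pairs (single- or
two-point, offspring rejected whenever either child repeats an index),
mutates every chromosome on a fixed period, evaluates new gene sets against
the gold-standard mapping, and carries the top elite fraction of offspring —
together with the incumbent best and a random refill back to the population
size — into the next generation.  Fitness values are cached by the unordered
gene set, so re-encountered subsets cost nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .distmap_core import BinaryCells, ScoreMatrix, mcc_scores
from .fitness_metrics import (
    FITNESS_MODES,
    AssignmentContext,
    FitnessVector,
    evaluate_fitness,
)
from .io_formats import BinaryAtlas, GeneSet

__all__ = [
    "Chromosome",
    "GAConfig",
    "GATrace",
    "SubsetEvaluator",
    "init_population",
    "crossover",
    "mutate",
    "evolve",
    "seed_robustness",
]


@dataclass
class Chromosome:
    """Fixed-length list of distinct 0-based gene indices plus cached fitness."""

    genes: tuple[int, ...]
    fitness: FitnessVector | None = None

    def __post_init__(self) -> None:
        self.genes = tuple(int(g) for g in self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("chromosome contains repeated gene indices")
        if any(g < 0 for g in self.genes):
            raise ValueError("gene indices must be non-negative")

    @property
    def key(self) -> frozenset[int]:
        """Identity for caching and duplicate detection (order-ignored)."""
        return frozenset(self.genes)

    def validate(self, n: int, panel_size: int) -> None:
        if len(self.genes) != n:
            raise ValueError(f"chromosome length {len(self.genes)} != {n}")
        if any(g >= panel_size for g in self.genes):
            raise ValueError("gene index exceeds panel size")


@dataclass
class GAConfig:
    """Hyperparameters of the evolution loop.

    Defaults follow the reference protocol: population 500, 100 crossovers
    per generation (200 offspring), mutation every third generation,
    top 20% elitism, single-point crossover.
    """

    n: int = 20
    pop_size: int = 500
    n_crossovers: int = 100
    mutation_period: int = 3
    elite_fraction: float = 0.20
    crossover_points: int = 1
    max_generations: int = 300
    seed: int = 0
    fitness_mode: str = "composite"
    top_k: int = 10
    plateau_tol: float = 1e-9
    plateau_patience: int = 50
    strict_pool: bool = False
    crossover_retry_factor: int = 20

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("subset size n must be >= 2")
        if self.pop_size < 2:
            raise ValueError("population size must be >= 2")
        if not 0 < self.elite_fraction <= 1:
            raise ValueError("elite_fraction must be in (0, 1]")
        if self.crossover_points not in (1, 2):
            raise ValueError("crossover_points must be 1 or 2")
        if self.fitness_mode not in FITNESS_MODES:
            raise ValueError(f"fitness_mode must be one of {FITNESS_MODES}")


@dataclass
class GATrace:
    """Per-generation best fitness and chromosome, plus the final pool."""

    best_fitness: list[float] = field(default_factory=list)
    best_vectors: list[FitnessVector] = field(default_factory=list)
    best_chromosomes: list[Chromosome] = field(default_factory=list)
    final_population: list[Chromosome] = field(default_factory=list)
    n_evaluations: int = 0

    @property
    def best(self) -> Chromosome:
        if not self.best_chromosomes:
            raise ValueError("empty trace")
        return self.best_chromosomes[-1]

    def last_unique_best(self, count: int = 3) -> list[Chromosome]:
        """The *count* most recent distinct best gene sets, newest first.

        These are the candidates handed to annotation-overlap
        re-prioritization after the run.
        """
        seen: set[frozenset[int]] = set()
        out: list[Chromosome] = []
        for chrom in reversed(self.best_chromosomes):
            if chrom.key not in seen:
                seen.add(chrom.key)
                out.append(chrom)
            if len(out) == count:
                break
        return out


class SubsetEvaluator:
    """Evaluates gene-index subsets against the gold-standard mapping.

    Holds the aligned binary cell and atlas matrices (full panel, same gene
    order) and the gold assignment context; fitness vectors are cached by
    unordered gene set.
    """

    def __init__(
        self,
        cells: BinaryCells,
        atlas: BinaryAtlas,
        ctx: AssignmentContext,
        top_k: int = 10,
    ) -> None:
        if cells.gene_ids != atlas.gene_ids:
            raise ValueError(
                "binarized cells and atlas must share an identical gene order"
            )
        self.gene_ids = list(atlas.gene_ids)
        self.cell_matrix = cells.values
        self.atlas_matrix = atlas.values
        self.cell_ids = list(cells.cell_ids)
        self.ctx = ctx
        self.top_k = top_k
        self._cache: dict[frozenset[int], FitnessVector] = {}
        self.n_evaluations = 0

    @property
    def panel_size(self) -> int:
        return len(self.gene_ids)

    def subset_scores(self, genes: tuple[int, ...]) -> ScoreMatrix:
        idx = np.asarray(genes, dtype=int)
        return ScoreMatrix(
            values=mcc_scores(self.cell_matrix[idx], self.atlas_matrix[idx]),
            gene_set_used=GeneSet(names=[self.gene_ids[i] for i in idx]),
            cell_ids=self.cell_ids,
        )

    def fitness(self, genes: tuple[int, ...]) -> FitnessVector:
        key = frozenset(genes)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        fv = evaluate_fitness(self.ctx, self.subset_scores(genes), k=self.top_k)
        if any(math.isnan(v) for v in (fv.s1, fv.s2, fv.s3, fv.s4, fv.composite)):
            raise ArithmeticError(f"NaN fitness for gene set {sorted(genes)}")
        self._cache[key] = fv
        self.n_evaluations += 1
        return fv

    def gene_set(self, chrom: Chromosome) -> GeneSet:
        return GeneSet(names=[self.gene_ids[i] for i in chrom.genes])


def _random_chromosome(n: int, panel_size: int, rng: np.random.Generator) -> Chromosome:
    return Chromosome(genes=tuple(rng.permutation(panel_size)[:n]))


def init_population(
    cfg: GAConfig, panel_size: int, rng: np.random.Generator
) -> list[Chromosome]:
    """pop_size uniformly random n-subsets of the panel, order randomized."""
    if cfg.n > panel_size:
        raise ValueError(
            f"subset size {cfg.n} exceeds panel size {panel_size}"
        )
    return [_random_chromosome(cfg.n, panel_size, rng) for _ in range(cfg.pop_size)]


def crossover(
    a: Chromosome,
    b: Chromosome,
    points: int | tuple[int, ...],
    cfg: GAConfig | None = None,
) -> list[Chromosome]:
    """Swap tails (single point) or middles (two points) of two parents.

    Offspring are returned only when *both* children are free of repeated
    indices; otherwise the crossover is rejected and an empty list returned.
    """
    if a is b:
        raise ValueError("self-crossover is not allowed")
    n = len(a.genes)
    if len(b.genes) != n:
        raise ValueError("parents must have equal length")
    if isinstance(points, int):
        points = (points,)
    if len(points) == 1:
        (p,) = points
        if not 1 <= p <= n - 1:
            raise ValueError(f"crossover point must be in [1, {n - 1}]")
        g1 = a.genes[:p] + b.genes[p:]
        g2 = b.genes[:p] + a.genes[p:]
    elif len(points) == 2:
        p, q = sorted(points)
        if not (1 <= p < q <= n - 1):
            raise ValueError("two-point crossover needs 1 <= p < q <= n-1")
        g1 = a.genes[:p] + b.genes[p:q] + a.genes[q:]
        g2 = b.genes[:p] + a.genes[p:q] + b.genes[q:]
    else:
        raise ValueError("points must be one or two cut positions")
    if len(set(g1)) != n or len(set(g2)) != n:
        return []
    return [Chromosome(genes=g1), Chromosome(genes=g2)]


def mutate(
    c: Chromosome, panel_size: int, rng: np.random.Generator
) -> Chromosome:
    """Replace one randomly chosen position with an index absent from the
    chromosome; exactly one position differs from the input."""
    n = len(c.genes)
    present = set(c.genes)
    candidates = [g for g in range(panel_size) if g not in present]
    if not candidates:
        raise ValueError("panel offers no replacement index for mutation")
    pos = int(rng.integers(n))
    new_gene = candidates[int(rng.integers(len(candidates)))]
    genes = list(c.genes)
    genes[pos] = new_gene
    return Chromosome(genes=tuple(genes))


def _random_points(n: int, how_many: int, rng: np.random.Generator) -> tuple[int, ...]:
    if how_many == 1:
        return (int(rng.integers(1, n)),)
    p, q = rng.choice(np.arange(1, n), size=2, replace=False)
    return tuple(sorted((int(p), int(q))))


def _make_offspring(
    pool: list[Chromosome], cfg: GAConfig, rng: np.random.Generator
) -> list[Chromosome]:
    """Collect 2*n_crossovers valid offspring, retrying rejected pairs up to
    a cap; on cap breach the generation proceeds short."""
    target = 2 * cfg.n_crossovers
    offspring: list[Chromosome] = []
    attempts = 0
    max_attempts = cfg.crossover_retry_factor * cfg.n_crossovers
    while len(offspring) < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.choice(len(pool), size=2, replace=False)
        points = _random_points(cfg.n, cfg.crossover_points, rng)
        offspring.extend(crossover(pool[i], pool[j], points))
    return offspring


def evolve(
    evaluator: SubsetEvaluator,
    cfg: GAConfig,
    rng: np.random.Generator | None = None,
    *,
    debug_checks: bool = False,
) -> GATrace:
    """Run the evolution loop and return its trace.

    Per generation: crossover offspring, periodic whole-population mutation,
    fitness evaluation of new gene sets, elitist selection with incumbent
    preservation, and random refill of the parent pool to ``pop_size``
    (``strict_pool=True`` keeps only the elite offspring, which lets the
    pool shrink).  Stops at ``max_generations`` or when the best fitness has
    not improved by more than ``plateau_tol`` for ``plateau_patience``
    generations.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    panel_size = evaluator.panel_size
    pool = init_population(cfg, panel_size, rng)
    for c in pool:
        c.fitness = evaluator.fitness(c.genes)

    def scalar(c: Chromosome) -> float:
        assert c.fitness is not None
        return c.fitness.scalar(cfg.fitness_mode)

    best = min(pool, key=scalar)
    trace = GATrace()
    trace.best_fitness.append(scalar(best))
    trace.best_vectors.append(best.fitness)  # type: ignore[arg-type]
    trace.best_chromosomes.append(best)

    stall = 0
    for gen in range(1, cfg.max_generations + 1):
        offspring = _make_offspring(pool, cfg, rng)
        if gen % cfg.mutation_period == 0 and panel_size > cfg.n:
            offspring = [mutate(c, panel_size, rng) for c in offspring]
        for c in offspring:
            c.fitness = evaluator.fitness(c.genes)
            if debug_checks:
                c.validate(cfg.n, panel_size)
        if not offspring:
            offspring = [best]
        offspring.sort(key=scalar)
        n_elite = max(1, int(round(cfg.elite_fraction * len(offspring))))
        elite = offspring[:n_elite]
        if cfg.strict_pool:
            pool = list(elite)
            if best not in pool:
                pool.append(best)
        else:
            pool = list(elite)
            if best.key not in {c.key for c in pool}:
                pool.append(best)
            while len(pool) < cfg.pop_size:
                fresh = _random_chromosome(cfg.n, panel_size, rng)
                fresh.fitness = evaluator.fitness(fresh.genes)
                pool.append(fresh)
        challenger = min(pool, key=scalar)
        if scalar(challenger) < scalar(best) - cfg.plateau_tol:
            best = challenger
            stall = 0
        else:
            stall += 1
        trace.best_fitness.append(scalar(best))
        trace.best_vectors.append(best.fitness)  # type: ignore[arg-type]
        trace.best_chromosomes.append(best)
        if stall >= cfg.plateau_patience:
            break
    trace.final_population = pool
    trace.n_evaluations = evaluator.n_evaluations
    return trace


def seed_robustness(
    evaluator: SubsetEvaluator,
    cfg: GAConfig,
    seeds: list[int],
) -> dict:
    """Re-run the GA under each seed and summarise dispersion of the final
    fitness vectors: per metric, the mean, variance, variance/mean ratio and
    coefficient of variation across seeds."""
    finals: list[FitnessVector] = []
    for seed in seeds:
        run_cfg = replace(cfg, seed=int(seed))
        trace = evolve(evaluator, run_cfg)
        finals.append(trace.best_vectors[-1])
    metrics = {
        "s1": [fv.s1 for fv in finals],
        "s2": [fv.s2 for fv in finals],
        "s3": [fv.s3 for fv in finals],
        "s4": [fv.s4 for fv in finals],
        "composite": [fv.composite for fv in finals],
    }
    summary = {}
    for name, vals in metrics.items():
        arr = np.asarray(vals, dtype=float)
        mean = float(arr.mean())
        var = float(arr.var(ddof=0)) if len(arr) > 1 else 0.0
        sd = float(np.sqrt(var))
        summary[name] = {
            "mean": mean,
            "variance": var,
            "variance_over_mean": var / mean if mean != 0 else 0.0,
            "cv": sd / mean if mean != 0 else 0.0,
        }
    return {"seeds": list(seeds), "finals": finals, "summary": summary}
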