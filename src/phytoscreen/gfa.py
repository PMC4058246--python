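"""Genetic-function-approximation descriptor-subset selection.

A seeded genetic algorithm searches subsets of a candidate descriptor pool
for the subset whose ordinary-least-squares fit best explains the activity.
Fitness is the training R² (or, optionally, Friedman's lack-of-fit score,
which penalizes model size and therefore tolerates an unbounded chromosome
length — plain R² never decreases when a column is added, so it requires a
length cap to be meaningful).

The GA is deliberately simple and fully reproducible: tournament selection
(size 2), single-point crossover on sorted gene lists with duplicate repair,
per-gene mutation that swaps a gene for a random unused descriptor, and
elitism of one. Ties between equal-fitness chromosomes are broken toward the
lexicographically smallest gene tuple so a fixed seed yields a bit-identical
trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .qsar import TrainingTable

NEG_INF = float("-inf")


@dataclass(frozen=True)
class Chromosome:
    """An ordered set of descriptor-pool indices with its cached fitness."""

    genes: tuple[int, ...]
    fitness: float = NEG_INF

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in chromosome {self.genes}")
        object.__setattr__(self, "genes", tuple(sorted(self.genes)))


@dataclass
class GfaConfig:
    population_size: int = 60
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    min_len: int = 2
    max_len: int = 6
    fixed_len: int | None = None  # mirror the published six-descriptor outcome
    fitness: str = "r2"  # or "lof"
    lof_smoothness: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population must be ≥ 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.fixed_len is not None:
            self.min_len = self.max_len = self.fixed_len


@dataclass
class GfaResult:
    best: Chromosome
    trace: list[float]
    population: list[Chromosome]
    selected_names: list[str] = field(default_factory=list)


def _ols_fitness(X: np.ndarray, y: np.ndarray, cfg: GfaConfig) -> float:
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    if n <= p or np.linalg.matrix_rank(A) < p + 1:
        return NEG_INF
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sse = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if cfg.fitness == "r2":
        return 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    if cfg.fitness == "lof":
        # Friedman lack-of-fit: SSE/(n·(1 − (c + d·p)/n)²); negated so larger is better
        c = p + 1
        shrink = 1.0 - (c + cfg.lof_smoothness * p) / n
        if shrink <= 0:
            return NEG_INF
        return -sse / (n * shrink**2)
    raise ValueError(f"unknown fitness {cfg.fitness!r}")


def gfa_fitness(ch: Chromosome, t: TrainingTable, cfg: GfaConfig) -> float:
    """Fitness of one chromosome: MLR on the selected columns.

    Rank-deficient selections get a −inf sentinel instead of an error so the
    GA can simply select against them.
    """
    return _ols_fitness(t.X[:, list(ch.genes)], t.y, cfg)


def _random_chromosome(rng: np.random.Generator, pool: int, cfg: GfaConfig) -> tuple[int, ...]:
    length = int(rng.integers(cfg.min_len, cfg.max_len + 1))
    return tuple(sorted(rng.choice(pool, size=length, replace=False).tolist()))


def _tournament(rng: np.random.Generator, pop: list[Chromosome]) -> Chromosome:
    i, j = rng.integers(0, len(pop), size=2)
    a, b = pop[int(i)], pop[int(j)]
    if a.fitness != b.fitness:
        return a if a.fitness > b.fitness else b
    return a if a.genes <= b.genes else b


def _crossover(rng: np.random.Generator, a: tuple[int, ...], b: tuple[int, ...],
               cfg: GfaConfig) -> tuple[int, ...]:
    """Single-point crossover on the sorted gene lists, repairing duplicates."""
    cut_a = int(rng.integers(0, len(a) + 1))
    cut_b = int(rng.integers(0, len(b) + 1))
    child: list[int] = list(a[:cut_a])
    for gene in b[cut_b:]:
        if gene not in child:
            child.append(gene)
    lo = max(cfg.min_len, 1)
    if len(child) < lo:
        donor = list(dict.fromkeys(g for g in (a + b) if g not in child))
        rng.shuffle(donor)
        child.extend(donor[: lo - len(child)])
    if len(child) > cfg.max_len:
        keep = rng.choice(len(child), size=cfg.max_len, replace=False)
        child = [child[int(i)] for i in sorted(keep)]
    return tuple(sorted(child))


def _mutate(rng: np.random.Generator, genes: tuple[int, ...], pool: int,
            cfg: GfaConfig) -> tuple[int, ...]:
    out = list(genes)
    for pos in range(len(out)):
        if rng.random() < cfg.mutation_rate:
            unused = [g for g in range(pool) if g not in out]
            if unused:
                out[pos] = int(rng.choice(unused))
    return tuple(sorted(out))


def _best(pop: list[Chromosome]) -> Chromosome:
    # highest fitness; ties toward the lexicographically smallest gene list
    return min(pop, key=lambda c: (-c.fitness, c.genes))


def run_gfa(t: TrainingTable, cfg: GfaConfig) -> GfaResult:
    """Run the GA over descriptor subsets of the training table.

    Returns the best chromosome, the per-generation best-fitness trace
    (non-decreasing thanks to elitism) and the final population. Reproducible
    bit-for-bit for a fixed ``cfg.seed``.
    """
    pool = t.k
    if pool < cfg.max_len:
        raise ValueError(f"descriptor pool ({pool}) smaller than max_len ({cfg.max_len})")
    rng = np.random.default_rng(cfg.seed)

    def evaluated(genes: tuple[int, ...]) -> Chromosome:
        ch = Chromosome(genes)
        return replace(ch, fitness=gfa_fitness(ch, t, cfg))

    population = [evaluated(_random_chromosome(rng, pool, cfg))
                  for _ in range(cfg.population_size)]
    trace = [_best(population).fitness]
    for _ in range(cfg.generations):
        elite = _best(population)
        children = [elite]
        while len(children) < cfg.population_size:
            p1 = _tournament(rng, population)
            p2 = _tournament(rng, population)
            genes = (
                _crossover(rng, p1.genes, p2.genes, cfg)
                if rng.random() < cfg.crossover_rate
                else p1.genes
            )
            genes = _mutate(rng, genes, pool, cfg)
            children.append(evaluated(genes))
        population = children
        trace.append(_best(population).fitness)
    best = _best(population)
    return GfaResult(
        best=best,
        trace=trace,
        population=population,
        selected_names=[t.names[g] for g in best.genes],
    )
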