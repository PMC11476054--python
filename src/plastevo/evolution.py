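"""The generational loop: fitness, selection, mutation, reproduction.

Reproduction is asexual with non-overlapping generations: each of the N
offspring copies the genome of one parent chosen by fitness-proportional
rejection sampling, then per-locus point mutation is applied.  Fitness is
the plasticity-inclusive complete-system count, so plastic completion of
a system confers a selective advantage even though acquired elements are
never inherited.

RNG protocol
------------
``run_simulation(params, seed)`` spawns three named substreams from the
master seed: ``map`` (genotype-phenotype map), ``init`` (generation-0
genomes) and ``evolution``.  The evolution stream spawns one child per
generation (generation 0 included); within a generation the draws occur
in a fixed order: N parent selections (scalar index/uniform pairs), one
mutation mask of shape (N, L) plus one shift vector over the mutated
positions in row-major order, then one uniform vector of length N per
plasticity trial.  Two runs with equal (params, seed) are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StateError
from .model_core import GenotypePhenotypeMap, build_gp_map, develop, express_population
from .params import ModelParams
from .plasticity import apply_plasticity_population
from .statistics import RUN_COLUMNS, RunSummary

logger = logging.getLogger("plastevo")

__all__ = [
    "PopulationState",
    "compute_fitness",
    "select_parent",
    "mutate",
    "mutate_population",
    "step_generation",
    "run_simulation",
]


@dataclass
class PopulationState:
    """Genomes, phenotypes and system counts of one generation.

    Attributes
    ----------
    genomes : ndarray of shape (N, L)
        Expressed allele per locus per individual.
    inherited : ndarray of bool, shape (N, P_e)
        Elements present via the genotype-phenotype map.
    plastic : ndarray of bool, shape (N, P_e)
        Elements acquired by plasticity this lifetime; elementwise
        disjoint from ``inherited``.
    n_fs_inherited, n_fs_total : ndarray of shape (N,)
        Complete leading systems using inherited elements only, and
        using inherited-or-plastic elements.
    generation : int
    """

    genomes: np.ndarray
    inherited: np.ndarray
    plastic: np.ndarray
    n_fs_inherited: np.ndarray
    n_fs_total: np.ndarray
    generation: int

    @property
    def N(self) -> int:
        return self.genomes.shape[0]


def compute_fitness(pop: PopulationState) -> np.ndarray:
    """Fitness vector: the plasticity-inclusive complete-system counts."""
    return np.asarray(pop.n_fs_total, dtype=np.int64).copy()


def select_parent(fitness: np.ndarray, rng: np.random.Generator,
                  max_fitness: int | None = None) -> int:
    """Pick one parent index by fitness-proportional rejection sampling.

    Repeat {draw a uniform candidate index, accept with probability
    ``fitness[i] / max(fitness)``} until accepted; the marginal selection
    probability is ``fitness[i] / sum(fitness)``.  When every fitness is
    zero the draw is uniform (the division-by-max rule is undefined and
    any fitness-blind rule is equivalent).
    """
    fitness = np.asarray(fitness)
    n = fitness.shape[0]
    if n == 0:
        raise StateError("cannot select a parent from an empty population")
    maxf = int(fitness.max()) if max_fitness is None else int(max_fitness)
    if maxf == 0:
        return int(rng.integers(n))
    while True:
        i = int(rng.integers(n))
        u = rng.random()
        if u * maxf < fitness[i]:
            return i


def mutate(genome: np.ndarray, params: ModelParams,
           rng: np.random.Generator) -> np.ndarray:
    """Point-mutate one genome: per locus, with probability ``mu``,
    replace the allele by a uniform draw from the other ``A - 1``.

    With ``A == 1`` there is no alternative allele and mutation is a
    no-op.  Always returns a copy.
    """
    genome = np.asarray(genome)
    out = genome.copy()
    if params.mu == 0.0 or params.A == 1:
        return out
    mask = rng.random(genome.shape[0]) < params.mu
    k = int(mask.sum())
    if k:
        shifts = rng.integers(1, params.A, size=k)
        out[mask] = (out[mask] + shifts) % params.A
    return out


def mutate_population(genomes: np.ndarray, params: ModelParams,
                      rng: np.random.Generator) -> np.ndarray:
    """Vectorized :func:`mutate` over an ``(N, L)`` matrix (row-major shifts)."""
    out = np.asarray(genomes).copy()
    if params.mu == 0.0 or params.A == 1:
        return out
    mask = rng.random(out.shape) < params.mu
    k = int(mask.sum())
    if k:
        shifts = rng.integers(1, params.A, size=k)
        out[mask] = (out[mask] + shifts) % params.A
    return out


def _develop_and_learn(genomes: np.ndarray, gp_map: GenotypePhenotypeMap,
                       params: ModelParams, rng: np.random.Generator,
                       generation: int) -> PopulationState:
    inherited = express_population(genomes, gp_map)
    n_inh = develop(inherited, params.C)
    plastic, n_tot = apply_plasticity_population(inherited, params, rng,
                                                 n_inherited=n_inh)
    return PopulationState(genomes=genomes, inherited=inherited,
                           plastic=plastic, n_fs_inherited=n_inh,
                           n_fs_total=n_tot, generation=generation)


def step_generation(pop: PopulationState, gp_map: GenotypePhenotypeMap,
                    params: ModelParams, rng: np.random.Generator) -> PopulationState:
    """Produce the next generation of exactly N offspring.

    Parent selection, genome copy, mutation, expression, development and
    plasticity, in that order; the offspring wholly replace the parents
    and plastic elements are never copied to offspring.
    """
    fitness = compute_fitness(pop)
    maxf = int(fitness.max())
    parents = np.fromiter(
        (select_parent(fitness, rng, max_fitness=maxf) for _ in range(pop.N)),
        dtype=np.int64, count=pop.N)
    genomes = mutate_population(pop.genomes[parents], params, rng)
    return _develop_and_learn(genomes, gp_map, params, rng,
                              generation=pop.generation + 1)


def _record(pop: PopulationState) -> tuple:
    return (pop.generation,
            int(pop.n_fs_inherited.max()), float(pop.n_fs_inherited.mean()),
            int(pop.n_fs_total.max()), float(pop.n_fs_total.mean()))


def run_simulation(params: ModelParams, seed: int | None = None,
                   keep_final_state: bool = True) -> RunSummary:
    """Run one full simulation and return its per-generation summary.

    The initial population draws every allele uniformly at random;
    generation 0 statistics are recorded before any selection acts, so
    the returned table has ``params.n_g + 1`` rows.  A keyboard
    interrupt stops the loop and returns the generations completed so
    far rather than discarding them.
    """
    if seed is None:
        seed = params.seed
    root = np.random.SeedSequence(seed)
    map_ss, init_ss, evo_ss = root.spawn(3)
    gp_map = build_gp_map(params, np.random.default_rng(map_ss))
    genomes = np.random.default_rng(init_ss).integers(
        0, params.A, size=(params.N, params.L))

    gen_rng = np.random.default_rng(evo_ss.spawn(1)[0])
    pop = _develop_and_learn(genomes, gp_map, params, gen_rng, generation=0)
    records = [_record(pop)]
    checkpoint = max(params.n_g // 10, 1)
    try:
        for _ in range(params.n_g):
            gen_rng = np.random.default_rng(evo_ss.spawn(1)[0])
            pop = step_generation(pop, gp_map, params, gen_rng)
            records.append(_record(pop))
            if pop.generation % checkpoint == 0:
                logger.debug(
                    "generation %d/%d: max_inherited=%d max_total=%d",
                    pop.generation, params.n_g,
                    int(pop.n_fs_inherited.max()), int(pop.n_fs_total.max()))
    except KeyboardInterrupt:
        logger.warning("interrupted at generation %d; returning partial run",
                       pop.generation)
    table = pd.DataFrame(records, columns=RUN_COLUMNS)
    return RunSummary(params=params, seed=int(seed), table=table,
                      final_state=pop if keep_final_state else None)
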