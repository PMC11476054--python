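"""Genotype-phenotype map, expression, and developmental assembly.

The genotype-phenotype map assigns every (locus, allele) pair one target
element uniformly at random; it represents the genetic architecture of a
run and is fixed for all individuals and generations.  Expression is a
logical OR over loci: an element is inherited-present iff at least one
locus carries an allele mapping to it.  With ``L`` loci over ``P_e``
elements this makes the marginal presence probability of an element in a
random genome ``1 - (1 - 1/P_e)**L`` (see :mod:`plastevo.analytics`).

Development assembles systems strictly in order: it walks the ``f``
blocks of ``C`` consecutive elements and stops at the first block with a
missing element.  Complete blocks beyond that point contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .params import ModelParams

__all__ = [
    "GenotypePhenotypeMap",
    "build_gp_map",
    "express",
    "express_population",
    "develop",
]


@dataclass(frozen=True)
class GenotypePhenotypeMap:
    """Fixed many-to-one map from (locus, allele) pairs to elements.

    Attributes
    ----------
    target : ndarray of shape (L, A)
        ``target[i, a]`` is the element index in ``[0, P_e)`` manifested
        when locus ``i`` expresses allele ``a``.
    P_e : int
        Number of phenotypic elements (size of the expression vector).
    """

    target: np.ndarray
    P_e: int

    @property
    def L(self) -> int:
        return self.target.shape[0]

    @property
    def A(self) -> int:
        return self.target.shape[1]


def build_gp_map(params: ModelParams, rng: np.random.Generator) -> GenotypePhenotypeMap:
    """Draw a genotype-phenotype map, uniform over elements per pair.

    Each of the ``L x A`` (locus, allele) pairs is independently assigned
    an element index drawn uniformly from ``[0, P_e)``.  The map is built
    once per run and shared by every individual.
    """
    target = rng.integers(0, params.P_e, size=(params.L, params.A))
    return GenotypePhenotypeMap(target=target, P_e=params.P_e)


def express(genome: np.ndarray, gp_map: GenotypePhenotypeMap) -> np.ndarray:
    """Expression of a single genome: OR of its loci's target elements.

    Returns a boolean vector of length ``P_e`` with element ``k`` set iff
    some locus ``i`` has ``gp_map.target[i, genome[i]] == k``.
    """
    genome = np.asarray(genome)
    if genome.shape != (gp_map.L,):
        raise DataError(f"genome must have shape ({gp_map.L},), got {genome.shape}")
    if genome.min(initial=0) < 0 or genome.max(initial=0) >= gp_map.A:
        raise DataError("allele index out of range")
    elements = gp_map.target[np.arange(gp_map.L), genome]
    out = np.zeros(gp_map.P_e, dtype=bool)
    out[elements] = True
    return out


def express_population(genomes: np.ndarray, gp_map: GenotypePhenotypeMap) -> np.ndarray:
    """Vectorized :func:`express` over an ``(N, L)`` genome matrix."""
    genomes = np.asarray(genomes)
    if genomes.ndim != 2 or genomes.shape[1] != gp_map.L:
        raise DataError(f"genomes must have shape (N, {gp_map.L})")
    if genomes.min(initial=0) < 0 or genomes.max(initial=0) >= gp_map.A:
        raise DataError("allele index out of range")
    n = genomes.shape[0]
    elements = gp_map.target[np.arange(gp_map.L)[None, :], genomes]
    out = np.zeros((n, gp_map.P_e), dtype=bool)
    out[np.arange(n)[:, None], elements] = True
    return out


def develop(elements: np.ndarray, C: int) -> np.ndarray | int:
    """Count complete leading functional systems of an element vector.

    System ``j`` (0-based) occupies elements ``[j*C, (j+1)*C)``.  The
    count is the length of the maximal prefix of systems whose elements
    are all present; a complete system after the first incomplete one
    does not count.

    Accepts a single ``(P_e,)`` vector (returns an int) or an
    ``(N, P_e)`` population matrix (returns an ``(N,)`` int array).
    """
    v = np.asarray(elements, dtype=bool)
    if v.shape[-1] % C != 0:
        raise DataError(f"element vector length {v.shape[-1]} not divisible by C={C}")
    f = v.shape[-1] // C
    complete = v.reshape(v.shape[:-1] + (f, C)).all(axis=-1)
    # argmin finds the first incomplete block; all-complete rows need f.
    n = np.where(complete.all(axis=-1), f, np.argmin(complete, axis=-1))
    if v.ndim == 1:
        return int(n)
    return n
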