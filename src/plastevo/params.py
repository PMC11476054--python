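"""Model parameters for the functional-systems evolution model.

The model organism is a linear hierarchy of ``f = P_e / C`` functional
systems, each a block of ``C`` binary phenotypic elements.  A genotype of
``L`` loci with ``A`` alleles per locus maps many-to-one onto the ``P_e``
elements; fitness is the number of consecutive complete systems counted
from the first.  Plasticity gives each individual ``t`` all-or-nothing
attempts per lifetime to fill the missing elements of its first incomplete
system, each missing element succeeding with probability ``p_e``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

from .errors import ParameterError


@dataclass(frozen=True)
class ModelParams:
    """Immutable parameter set for one simulation run.

    Parameters
    ----------
    N : int
        Population size (constant; non-overlapping generations).
    n_g : int
        Number of generations to simulate (generation 0 is the random
        initial population, so trajectories have ``n_g + 1`` points).
    L : int
        Number of loci in the genotype.
    A : int
        Number of alleles per locus.
    P_e : int
        Total number of phenotypic elements; must be a multiple of ``C``.
    C : int
        Elements per functional system (phenotypic complexity of one
        system).
    mu : float
        Per-locus point-mutation probability per reproduction.
    p_e : float
        Per-element fill probability during one plasticity trial.
    t : int
        Number of plasticity (learning) trials per lifetime; ``t = 0``
        disables plasticity.
    seed : int
        Default RNG seed used by :func:`plastevo.evolution.run_simulation`
        when no explicit seed is given.
    """

    N: int = 500
    n_g: int = 25_000
    L: int = 4000
    A: int = 5
    P_e: int = 2000
    C: int = 20
    mu: float = 2e-4
    p_e: float = 0.5
    t: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("N", "L", "A", "P_e", "C"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 1:
                raise ParameterError(f"{name} must be a positive integer, got {v!r}")
        for name in ("n_g", "t", "seed"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ParameterError(f"{name} must be a non-negative integer, got {v!r}")
        if self.P_e % self.C != 0:
            raise ParameterError(
                f"P_e ({self.P_e}) must be divisible by C ({self.C})"
            )
        # Genetic redundancy: enough (locus, allele) pairs to encode every
        # element; presets use the strict L*A > P_e so that alternative
        # genetic variants encode the same element.
        if self.L * self.A < self.P_e:
            raise ParameterError(
                f"L*A ({self.L * self.A}) must be at least P_e ({self.P_e})"
            )
        if not 0.0 <= self.mu <= 1.0:
            raise ParameterError(f"mu must lie in [0, 1], got {self.mu!r}")
        if not 0.0 <= self.p_e <= 1.0:
            raise ParameterError(f"p_e must lie in [0, 1], got {self.p_e!r}")

    @property
    def f(self) -> int:
        """Number of functional systems per individual (``P_e / C``)."""
        return self.P_e // self.C

    def with_(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)
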