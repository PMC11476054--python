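"""Closed-form expectations for the randomly initialized population.

With L loci each independently mapped (per expressed allele) to one of
P_e elements, the probability that a given element is present in a
uniformly random genome is

    p_rnd = 1 - (1 - 1/P_e)**L,

and the expected number of missing elements in a not-yet-complete system
of C elements is m = C * (1 - p_rnd).  These two quantities set the
initial difficulty of a plasticity trial: the per-trial completion
probability is p_e**m (see :mod:`plastevo.plasticity`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .params import ModelParams

__all__ = ["InitExpectation", "p_rnd_analytic", "expected_missing"]


def p_rnd_analytic(L: int, P_e: int) -> float:
    """Probability an element is present in a random initial genome."""
    if L < 1:
        raise ParameterError(f"L must be >= 1, got {L}")
    if P_e < 1:
        raise ParameterError(f"P_e must be >= 1, got {P_e}")
    if P_e == 1:
        return 1.0
    # -expm1(L*log1p(-1/P_e)) evaluates 1-(1-1/P_e)**L stably for large L.
    return float(-np.expm1(L * np.log1p(-1.0 / P_e)))


def expected_missing(C: int, p_rnd: float) -> float:
    """Expected missing elements, C*(1-p_rnd), in an incomplete system."""
    if C < 1:
        raise ParameterError(f"C must be >= 1, got {C}")
    return C * (1.0 - p_rnd)


@dataclass(frozen=True)
class InitExpectation:
    """Initialization expectations for a parameter set."""

    p_rnd: float
    m_expected: float

    @classmethod
    def from_params(cls, params: ModelParams) -> "InitExpectation":
        p = p_rnd_analytic(params.L, params.P_e)
        return cls(p_rnd=p, m_expected=expected_missing(params.C, p))
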