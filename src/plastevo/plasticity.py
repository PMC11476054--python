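"""Within-lifetime plasticity: all-or-nothing completion of the terminal system.

Each individual gets ``t`` trials per lifetime.  A trial targets the
terminal system — the first system not complete under the union of
inherited and already-acquired elements.  If that system misses ``m``
elements, the trial succeeds with probability ``p_e**m`` (every missing
element must fill, each independently with probability ``p_e``); on
success all ``m`` elements are acquired at once, on failure nothing is
kept, so partial fills never persist between trials and the per-trial
success law is exactly ``p_e**m``.  A successful trial completes exactly
one system; remaining trials move on to the next.  Acquired elements are
phenotypic only — they are never written back to the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model_core import develop
from .params import ModelParams

__all__ = ["PlasticityOutcome", "completion_probability", "apply_plasticity",
           "apply_plasticity_population"]


@dataclass(frozen=True)
class PlasticityOutcome:
    """Result of one individual's plasticity phase.

    Attributes
    ----------
    plastic : ndarray of bool, shape (P_e,)
        Elements acquired by plasticity; disjoint from the inherited
        vector by construction.
    systems_completed : int
        Number of systems completed by plasticity (== successful trials).
    trials_used : int
        Trials actually attempted; less than ``t`` only when all ``f``
        systems were complete before the trials ran out.
    """

    plastic: np.ndarray
    systems_completed: int
    trials_used: int


def completion_probability(m: int, p_e: float) -> float:
    """Probability ``p_e**m`` that one trial completes a system missing ``m`` elements."""
    if m < 0:
        raise ParameterError(f"m must be non-negative, got {m}")
    if not 0.0 <= p_e <= 1.0:
        raise ParameterError(f"p_e must lie in [0, 1], got {p_e}")
    return float(p_e) ** int(m)


def apply_plasticity(
    inherited: np.ndarray, params: ModelParams, rng: np.random.Generator
) -> PlasticityOutcome:
    """Run ``params.t`` plasticity trials for a single individual.

    Each trial draws one uniform variate and succeeds iff it falls below
    ``p_e**m`` for the current terminal system, which is the exact
    distribution of "all m missing elements fill independently".
    """
    inherited = np.asarray(inherited, dtype=bool)
    C, f = params.C, params.f
    plastic = np.zeros_like(inherited)
    n = develop(inherited, C)
    trials_used = 0
    completed = 0
    for _ in range(params.t):
        if n >= f:
            break
        trials_used += 1
        block = slice(n * C, (n + 1) * C)
        present = inherited[block] | plastic[block]
        m = C - int(present.sum())
        if rng.random() < params.p_e**m:
            plastic[block] |= ~present
            completed += 1
            # development resumes and may pass straight through any
            # subsequent systems that are already complete
            n = develop(inherited | plastic, C)
    return PlasticityOutcome(plastic=plastic, systems_completed=completed,
                             trials_used=trials_used)


def apply_plasticity_population(
    inherited: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    n_inherited: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized plasticity phase over an ``(N, P_e)`` population.

    Returns ``(plastic, n_total)`` where ``plastic`` is the acquired
    element matrix and ``n_total`` the per-individual count of complete
    systems under inherited-or-plastic elements.

    RNG protocol: exactly one uniform vector of length ``N`` is drawn per
    trial, whether or not individuals are still active, so the stream
    layout depends only on ``(N, t)``.
    """
    inherited = np.asarray(inherited, dtype=bool)
    N = inherited.shape[0]
    C, f = params.C, params.f
    plastic = np.zeros_like(inherited)
    n = np.array(develop(inherited, C) if n_inherited is None else n_inherited,
                 dtype=np.int64, copy=True)
    offsets = np.arange(C)
    for _ in range(params.t):
        u = rng.random(N)
        rows = np.nonzero(n < f)[0]
        if rows.size == 0:
            continue
        cols = n[rows, None] * C + offsets[None, :]
        present = inherited[rows[:, None], cols] | plastic[rows[:, None], cols]
        m = C - present.sum(axis=1)
        success = u[rows] < params.p_e ** m
        srows = rows[success]
        if srows.size:
            missing = ~present[success]
            plastic[np.repeat(srows, C)[missing.ravel()],
                    cols[success].ravel()[missing.ravel()]] = True
            # recompute the prefix: development passes straight through
            # subsequent systems that were already complete
            n[srows] = develop(inherited[srows] | plastic[srows], C)
    return plastic, n
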