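"""Run and ensemble summaries: trajectories, waiting times, acceleration.

The headline quantity throughout is the per-generation population maximum
of the inherited complete-system count ("max_inherited"); the plasticity-
inclusive count ("max_total") and population means are recorded alongside.
Ensemble statistics are means over replicate runs with normal-approximation
95% confidence limits (mean +/- 1.96 SE over replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, StateError
from .params import ModelParams

__all__ = [
    "RunSummary",
    "EnsembleSummary",
    "ensemble_summary",
    "generations_to_k",
    "acceleration_ratio",
    "inherited_proportion_profile",
    "inherited_proportion_ensemble",
    "shadowing_summary",
]

#: z-quantile for two-sided 95% confidence limits.
Z95 = 1.96

RUN_COLUMNS = ["generation", "max_inherited", "mean_inherited",
               "max_total", "mean_total"]


@dataclass(frozen=True)
class RunSummary:
    """Per-generation statistics of a single simulation run.

    Attributes
    ----------
    params : ModelParams
        Parameter echo for the run.
    seed : int
        Seed the run was executed with.
    table : DataFrame
        One row per generation (``n_g + 1`` rows) with columns
        ``generation, max_inherited, mean_inherited, max_total,
        mean_total``.
    final_state : object or None
        The final :class:`~plastevo.evolution.PopulationState`, kept so
        element-level profiles can be computed without re-running.
    """

    params: ModelParams
    seed: int
    table: pd.DataFrame
    final_state: object | None = field(default=None, compare=False, repr=False)

    @property
    def max_inherited(self) -> np.ndarray:
        return self.table["max_inherited"].to_numpy()

    @property
    def max_total(self) -> np.ndarray:
        return self.table["max_total"].to_numpy()

    @property
    def final_max_inherited(self) -> float:
        return float(self.table["max_inherited"].iloc[-1])

    @property
    def final_max_total(self) -> float:
        return float(self.table["max_total"].iloc[-1])


@dataclass(frozen=True)
class EnsembleSummary:
    """Replicate-ensemble statistics of one experimental condition.

    ``table`` has one row per generation with, for each of
    ``max_inherited`` and ``max_total``, the replicate mean and 95%
    confidence limits (``<col>_mean``, ``<col>_lo``, ``<col>_hi``).
    """

    n_replicates: int
    table: pd.DataFrame
    params: ModelParams | None = None

    @property
    def mean_max_inherited(self) -> np.ndarray:
        return self.table["max_inherited_mean"].to_numpy()

    @property
    def mean_max_total(self) -> np.ndarray:
        return self.table["max_total_mean"].to_numpy()

    @property
    def final_max_inherited(self) -> float:
        return float(self.table["max_inherited_mean"].iloc[-1])

    @property
    def final_max_total(self) -> float:
        return float(self.table["max_total_mean"].iloc[-1])


def ensemble_summary(runs: Sequence[RunSummary]) -> EnsembleSummary:
    """Combine replicate runs into per-generation means with 95% limits."""
    if not runs:
        raise StateError("cannot summarize an empty replicate list")
    n = len(runs)
    gens = runs[0].table["generation"].to_numpy()
    for r in runs[1:]:
        if len(r.table) != len(gens):
            raise StateError("replicates have unequal trajectory lengths")
    out = {"generation": gens}
    for col in ("max_inherited", "mean_inherited", "max_total", "mean_total"):
        stack = np.stack([r.table[col].to_numpy() for r in runs])
        mean = stack.mean(axis=0)
        se = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
        out[f"{col}_mean"] = mean
        out[f"{col}_lo"] = mean - Z95 * se
        out[f"{col}_hi"] = mean + Z95 * se
    return EnsembleSummary(n_replicates=n, table=pd.DataFrame(out),
                           params=runs[0].params)


def generations_to_k(trajectory: Sequence[float], k: float) -> int | None:
    """First generation index at which the trajectory reaches ``k``.

    Returns ``None`` if the trajectory never reaches ``k``.
    """
    if k < 0:
        raise ParameterError(f"k must be non-negative, got {k}")
    traj = np.asarray(trajectory, dtype=float)
    if traj.size == 0:
        raise StateError("empty trajectory")
    hits = np.nonzero(traj >= k)[0]
    return int(hits[0]) if hits.size else None


def acceleration_ratio(
    noplast: EnsembleSummary,
    plast: EnsembleSummary,
    k_grid: Iterable[float] | None = None,
) -> float:
    """Average waiting-time ratio (no plasticity / plasticity) over a k-grid.

    For each threshold ``k``, the ratio of the number of generations each
    condition's ensemble-mean population-max inherited-systems trajectory
    needs to reach ``k``.  When ``k_grid`` is omitted it defaults to every
    integer ``k`` reached by both conditions strictly after generation 0
    (levels already present at initialization measure no evolution and
    would give a 0/0 ratio).
    """
    traj_np = noplast.mean_max_inherited
    traj_p = plast.mean_max_inherited
    if k_grid is None:
        kmax = int(min(traj_np.max(), traj_p.max()))
        k_grid = range(1, kmax + 1)
    ratios = []
    for k in k_grid:
        g_np = generations_to_k(traj_np, k)
        g_p = generations_to_k(traj_p, k)
        if g_np is None or g_p is None or g_np == 0 or g_p == 0:
            continue
        ratios.append(g_np / g_p)
    if not ratios:
        raise StateError("no common k threshold reached by both conditions")
    return float(np.mean(ratios))


def inherited_proportion_profile(pop, params: ModelParams,
                                 max_offset: int | None = None) -> pd.DataFrame:
    """Fraction of inherited elements in systems beyond the last complete one.

    For each individual, system-rank offset 1 is its first incomplete
    system (under inherited elements only), offset 2 the next, and so on.
    The reported proportion at each offset is the population average of
    the inherited-present fraction of that system's ``C`` elements,
    taken over the individuals for which the offset exists (truncated at
    the last system).  Returns a DataFrame with columns ``offset,
    proportion, n_individuals``.
    """
    C, f = params.C, params.f
    inherited = np.asarray(pop.inherited, dtype=bool)
    last = np.asarray(pop.n_fs_inherited)
    if max_offset is None:
        max_offset = f
    offsets_c = np.arange(C)
    rows = []
    for off in range(1, max_offset + 1):
        sys_idx = last + off - 1
        valid = sys_idx < f
        if not valid.any():
            break
        idx = np.nonzero(valid)[0]
        cols = sys_idx[idx, None] * C + offsets_c[None, :]
        frac = inherited[idx[:, None], cols].mean(axis=1)
        rows.append((off, float(frac.mean()), int(idx.size)))
    return pd.DataFrame(rows, columns=["offset", "proportion", "n_individuals"])


def inherited_proportion_ensemble(
    pops: Sequence, params: ModelParams, max_offset: int | None = None
) -> pd.DataFrame:
    """Replicate-averaged element profile with 95% confidence limits."""
    profiles = [inherited_proportion_profile(p, params, max_offset) for p in pops]
    merged = pd.concat(profiles).groupby("offset")["proportion"]
    mean = merged.mean()
    count = merged.count()
    se = merged.std(ddof=1).fillna(0.0) / np.sqrt(count)
    return pd.DataFrame({
        "offset": mean.index,
        "proportion_mean": mean.to_numpy(),
        "proportion_lo": (mean - Z95 * se).to_numpy(),
        "proportion_hi": (mean + Z95 * se).to_numpy(),
        "n_replicates": count.to_numpy(),
    }).reset_index(drop=True)


def shadowing_summary(ensembles_by_t: Mapping[int, EnsembleSummary]) -> pd.DataFrame:
    """Final inherited-systems count per learning-trial budget ``t``.

    Tabulates, for each plasticity level, the ensemble-mean population-max
    inherited complete-system count at the last generation.  A decline at
    high ``t`` is the shadowing effect: abundant plasticity completes
    systems phenotypically and weakens selection for genetic assimilation.
    """
    rows = [(t, ens.final_max_inherited, ens.final_max_total, ens.n_replicates)
            for t, ens in sorted(ensembles_by_t.items())]
    return pd.DataFrame(rows, columns=["t", "final_max_inherited",
                                       "final_max_total", "n_replicates"])
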