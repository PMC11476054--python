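"""Experiment orchestration: presets, config files, replicate ensembles.

An experiment is a grid of conditions (system complexity C, mutation
rate mu, plasticity trials t) crossed with independently seeded
replicates.  Outputs are long-format CSV tables (one row per generation
per replicate per condition), per-condition ensemble CSVs, and a JSON
manifest that records every parameter and derived seed so a rerun
reproduces all tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ParameterError
from .params import ModelParams
from .evolution import run_simulation
from .statistics import EnsembleSummary, RunSummary, ensemble_summary

logger = logging.getLogger("plastevo")

__all__ = ["ExperimentConfig", "PRESETS", "load_config", "run_experiment",
           "condition_label"]

_CONFIG_KEYS = {"name", "N", "n_g", "L", "A", "P_e", "C", "mu", "p_e", "t",
                "replicates", "seed", "seeds"}


@dataclass(frozen=True)
class ExperimentConfig:
    """A validated experiment: base parameters plus condition grids."""

    name: str = "custom"
    N: int = 500
    n_g: int = 25_000
    L: int = 4000
    A: int = 5
    P_e: int = 2000
    p_e: float = 0.5
    C: tuple[int, ...] = (20,)
    mu: tuple[float, ...] = (2e-4,)
    t: tuple[int, ...] = (0, 10)
    replicates: int = 10
    seed: int = 0
    seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for grid_name in ("C", "mu", "t"):
            if len(getattr(self, grid_name)) == 0:
                raise ConfigError(f"{grid_name}: grid must be non-empty")
        if self.replicates < 1:
            raise ConfigError(f"replicates: must be >= 1, got {self.replicates}")
        if self.seeds is not None:
            if len(self.seeds) != self.replicates:
                raise ConfigError(
                    f"seeds: expected {self.replicates} entries "
                    f"(one per replicate), got {len(self.seeds)}")
            if len(set(self.seeds)) != len(self.seeds):
                raise ConfigError("seeds: replicate seeds must be unique")
        # Building the params validates every condition cell.
        for c, m, t in self.conditions():
            try:
                self.model_params(c, m, t)
            except ParameterError as exc:
                raise ConfigError(f"condition C={c}, mu={m}, t={t}: {exc}") from exc

    def conditions(self) -> list[tuple[int, float, int]]:
        """The (C, mu, t) grid in deterministic order."""
        return list(itertools.product(self.C, self.mu, self.t))

    def model_params(self, C: int, mu: float, t: int) -> ModelParams:
        return ModelParams(N=self.N, n_g=self.n_g, L=self.L, A=self.A,
                           P_e=self.P_e, C=C, mu=mu, p_e=self.p_e, t=t,
                           seed=self.seed)

    def replicate_seed(self, C: int, mu: float, t: int, rep: int) -> int:
        """Deterministic per-run seed, independent of grid ordering."""
        base = self.seeds[rep] if self.seeds is not None else self.seed
        tag = zlib.crc32(f"C={C};mu={mu!r};t={t};rep={rep}".encode())
        ss = np.random.SeedSequence([int(base), tag])
        return int(ss.generate_state(1)[0] % (2**31))

    def scaled(self, factor: int) -> "ExperimentConfig":
        """Desk-scale the experiment: divide N, n_g, L and P_e by ``factor``.

        The C, mu and t grids and p_e are kept, so divisibility of the
        scaled P_e by every C is re-validated.
        """
        if factor < 1:
            raise ConfigError(f"scale factor must be >= 1, got {factor}")
        if factor == 1:
            return self
        return dataclasses.replace(
            self, name=f"{self.name}-x{factor}",
            N=max(self.N // factor, 2), n_g=max(self.n_g // factor, 1),
            L=max(self.L // factor, 1), P_e=max(self.P_e // factor, 1))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["C"] = list(self.C)
        d["mu"] = list(self.mu)
        d["t"] = list(self.t)
        d["seeds"] = list(self.seeds) if self.seeds is not None else None
        return d


def _as_tuple(value: Any, kind: type) -> tuple:
    if isinstance(value, (list, tuple)):
        return tuple(kind(v) for v in value)
    return (kind(value),)


def _make_config(raw: Mapping[str, Any], defaults: "ExperimentConfig") -> ExperimentConfig:
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kw: dict[str, Any] = {}
    for key in ("name",):
        if key in raw:
            kw[key] = str(raw[key])
    for key in ("N", "n_g", "L", "A", "P_e", "replicates", "seed"):
        if key in raw:
            try:
                kw[key] = int(raw[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{key}: expected an integer, got {raw[key]!r}") from exc
    if "p_e" in raw:
        kw["p_e"] = float(raw["p_e"])
    if "C" in raw:
        kw["C"] = _as_tuple(raw["C"], int)
    if "mu" in raw:
        kw["mu"] = _as_tuple(raw["mu"], float)
    if "t" in raw:
        kw["t"] = _as_tuple(raw["t"], int)
    if "seeds" in raw and raw["seeds"] is not None:
        kw["seeds"] = _as_tuple(raw["seeds"], int)
    return dataclasses.replace(defaults, **kw)


def load_config(path: str | Path,
                defaults: ExperimentConfig | None = None) -> ExperimentConfig:
    """Load a YAML experiment config; missing keys fall back to the
    standard paired plastic/non-plastic preset (``fig2``).

    An empty file therefore yields the full default experiment.  Unknown
    keys are rejected with the offending names.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    if defaults is None:
        defaults = PRESETS["fig2"]
    return _make_config(raw, defaults)


_MINI = dict(N=100, n_g=2000, L=400, A=5, P_e=200, replicates=3)

#: Named experiment grids.  The full-scale presets reproduce the headline
#: ensembles (hours of compute); the ``-mini`` presets are desk-scale
#: versions with the same locus-to-element ratio (L/P_e = 2, hence the
#: same initial element probability p_rnd) for quick runs and CI.
PRESETS: dict[str, ExperimentConfig] = {
    "fig2": ExperimentConfig(name="fig2", C=(20,), mu=(2e-4,), t=(0, 10)),
    "fig3a": ExperimentConfig(name="fig3a", C=(10, 20, 40),
                              mu=(1e-6, 1e-5, 1e-4, 1e-3), t=(0, 10)),
    "fig3b": ExperimentConfig(name="fig3b", C=(10, 20, 40),
                              mu=(1e-6, 1e-5, 1e-4, 1e-3), t=(0, 10)),
    "fig4": ExperimentConfig(name="fig4", C=(40,), mu=(1e-5, 1e-4, 1e-3),
                             t=(0, 1, 5, 10)),
    "fig2-mini": ExperimentConfig(name="fig2-mini", C=(10,), mu=(2e-4,),
                                  t=(0, 10), **_MINI),
    "fig3a-mini": ExperimentConfig(name="fig3a-mini", C=(5, 10, 20),
                                   mu=(2e-4,), t=(0, 10), **_MINI),
}


def condition_label(C: int, mu: float, t: int) -> str:
    return f"C{C}_mu{mu:g}_t{t}"


def run_experiment(config: ExperimentConfig, outdir: str | Path,
                   scale: int = 1) -> dict[str, EnsembleSummary]:
    """Run every (condition x replicate) cell and write tables.

    Writes ``runs/<condition>_rep<k>.csv`` per run (skipped when already
    present, making interrupted experiments resumable per completed run),
    ``ensemble_<condition>.csv`` per condition, and ``manifest.json``.
    Returns the per-condition ensemble summaries keyed by label.
    """
    config = config.scaled(scale)
    outdir = Path(outdir)
    rundir = outdir / "runs"
    rundir.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "package": "plastevo", "version": __version__,
        "config": config.to_dict(), "scale": scale,
        "runs": [],
        "notes": {
            "plastic_t": "paired plastic condition uses the largest t in the grid",
            "mu_grid": "one value per decade when a range is swept",
            "profile_weighting": "population-weighted averaging",
        },
    }
    ensembles: dict[str, EnsembleSummary] = {}
    for C, mu, t in config.conditions():
        label = condition_label(C, mu, t)
        params = config.model_params(C, mu, t)
        runs: list[RunSummary] = []
        for rep in range(config.replicates):
            seed = config.replicate_seed(C, mu, t, rep)
            run_path = rundir / f"{label}_rep{rep}.csv"
            try:
                if run_path.exists():
                    logger.info("reusing %s", run_path)
                    table = pd.read_csv(run_path).drop(
                        columns=["condition", "replicate"])
                    runs.append(RunSummary(params=params, seed=seed,
                                           table=table))
                else:
                    logger.info("running %s rep %d (seed %d)", label, rep, seed)
                    run = run_simulation(params, seed=seed,
                                         keep_final_state=False)
                    out = run.table.copy()
                    out.insert(0, "condition", label)
                    out.insert(1, "replicate", rep)
                    out.to_csv(run_path, index=False)
                    runs.append(run)
            except OSError as exc:
                # a failed cell is reported but must not abort the grid
                logger.error("cell %s rep %d failed: %s", label, rep, exc)
                manifest["runs"].append({"condition": label, "replicate": rep,
                                         "seed": seed, "error": str(exc)})
                continue
            manifest["runs"].append({"condition": label, "replicate": rep,
                                     "seed": seed, "file": f"runs/{run_path.name}"})
        if not runs:
            logger.error("condition %s produced no usable runs", label)
            continue
        ens = ensemble_summary(runs)
        ens.table.to_csv(outdir / f"ensemble_{label}.csv", index=False)
        ensembles[label] = ens
        logger.info("condition %s done: final max_inherited %.2f",
                    label, ens.final_max_inherited)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return ensembles
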