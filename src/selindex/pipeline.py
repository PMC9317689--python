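"""End-to-end pipeline: simulate -> estimate -> sweep -> select -> report.

Each stage reads and writes only documented delimited-text artifacts inside
a run directory, so any stage can be re-run from saved intermediates and
yield the same outputs as a full run.  The run manifest records the seed,
configuration hash and package version; identical config + seed gives
byte-identical numeric tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimation import compute_blues, covariance_matrices
from .indices import RestrictionSpec, selection_intensity
from .io import read_matrix, read_table, read_trial, write_matrix, write_table, write_trial
from .select import SelectionSet, consistency_analysis, select_top_fraction
from .simulate import default_wheat_spec, simulate_met
from .sweep import (
    SelectionCriteria,
    WeightGrid,
    default_grid,
    evaluate_grid,
    select_best_weights,
)
from .indices import index_values, restricted_coefficients

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "estimate", "sweep", "best-weights", "select", "report")

#: scenario shorthand accepted in configs
SCENARIO_ALIASES = {
    "lpsi": RestrictionSpec(),
    "rlpsi-yield": RestrictionSpec(restricted=("yield",)),
    "rlpsi-gpc": RestrictionSpec(restricted=("gpc",)),
}


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable stage name and code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    outdir: Path
    seed: int = 0
    n_genotypes: int = 196
    input_trial: Path | None = None  # real data instead of simulation
    grid: str | dict = "default"  # "default" or {trait: [levels...]}
    scenarios: tuple[str, ...] = ("lpsi", "rlpsi-yield", "rlpsi-gpc")
    fraction: float = 0.10
    top_n_weights: int = 5
    rank_trait: str = "yield"
    criteria: dict = field(default_factory=dict)
    min_weights: int | None = None  # default: all shortlisted weights
    min_scenarios: int = 2
    management_specific_cp: bool = True
    finite_intensity: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must be in (0, 1)")
        for s in self.scenarios:
            if s not in SCENARIO_ALIASES:
                raise ValueError(f"unknown scenario {s!r}; choose from "
                                 f"{sorted(SCENARIO_ALIASES)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "scenarios" in raw:
            raw["scenarios"] = tuple(raw["scenarios"])
        return cls(**raw)

    def hash(self) -> str:
        # outdir is where the run lands, not what it computes
        payload = {k: str(v) for k, v in sorted(self.__dict__.items())
                   if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def weight_grid(self) -> WeightGrid:
        if self.grid == "default":
            return default_grid()
        return WeightGrid(levels={t: tuple(v) for t, v in self.grid.items()})

    def selection_criteria(self) -> SelectionCriteria:
        c = self.criteria
        return SelectionCriteria(
            max_gain={k: float(v) for k, v in c.get("max_gain", {}).items()},
            min_gain={k: float(v) for k, v in c.get("min_gain", {}).items()},
            min_response=float(c.get("min_response", -np.inf)),
            min_correlation=float(c.get("min_correlation", -np.inf)),
        )


def _paths(cfg: PipelineConfig) -> dict[str, Path]:
    d = cfg.outdir
    return {
        "trial": d / "trial.csv",
        "truth": d / "truth.csv",
        "sweep": d / "sweep.csv",
        "best": d / "best_weights.csv",
        "selections": d / "selection_sets.csv",
        "consistency": d / "consistency.csv",
        "manifest": d / "manifest.json",
        "anova": d / "weight_anova.txt",
    }


def _blue_path(cfg: PipelineConfig, label: str) -> Path:
    return cfg.outdir / f"blues_{label}.csv"


def _cp_paths(cfg: PipelineConfig, label: str) -> tuple[Path, Path]:
    return cfg.outdir / f"C_{label}.csv", cfg.outdir / f"P_{label}.csv"


def _datasets(trial) -> list[str]:
    return trial.managements + ["combined"]


def stage_simulate(cfg: PipelineConfig):
    p = _paths(cfg)
    if cfg.input_trial is not None:
        trial = read_trial(cfg.input_trial)
    else:
        spec = default_wheat_spec(cfg.seed)
        if cfg.n_genotypes != spec.n_genotypes:
            from dataclasses import replace

            spec = replace(spec, n_genotypes=cfg.n_genotypes)
        trial = simulate_met(spec)
    write_trial(trial, p["trial"], truth_path=p["truth"], seed=cfg.seed,
                config_hash=cfg.hash())
    return trial


def stage_estimate(cfg: PipelineConfig):
    p = _paths(cfg)
    trial = read_trial(p["trial"], truth_path=p["truth"])
    for label in _datasets(trial):
        blues = compute_blues(trial, label)
        write_table(blues.values, _blue_path(cfg, label), seed=cfg.seed,
                    config_hash=cfg.hash(), index=True)
        cp = covariance_matrices(trial, label)
        c_path, p_path = _cp_paths(cfg, label)
        write_matrix(cp.C, c_path, seed=cfg.seed, config_hash=cfg.hash())
        write_matrix(cp.P, p_path, seed=cfg.seed, config_hash=cfg.hash())


def _intensity(cfg: PipelineConfig, n: int) -> float:
    return selection_intensity(cfg.fraction, n=n if cfg.finite_intensity else None)


def stage_sweep(cfg: PipelineConfig):
    p = _paths(cfg)
    c_path, p_path = _cp_paths(cfg, "combined")
    C, P = read_matrix(c_path), read_matrix(p_path)
    grid = cfg.weight_grid()
    blues = read_table(_blue_path(cfg, "combined"), index_col=0)
    k = _intensity(cfg, len(blues))
    scenarios = [SCENARIO_ALIASES[s] for s in cfg.scenarios]
    rows = evaluate_grid(grid, C.values, P.values, scenarios, k,
                         trait_names=tuple(C.columns))
    write_table(rows, p["sweep"], seed=cfg.seed, config_hash=cfg.hash())


def stage_best_weights(cfg: PipelineConfig):
    p = _paths(cfg)
    rows = read_table(p["sweep"])
    best = select_best_weights(rows, cfg.selection_criteria(),
                               top_n=cfg.top_n_weights,
                               rank_trait=cfg.rank_trait)
    write_table(best, p["best"], seed=cfg.seed, config_hash=cfg.hash())
    # per-factor one-way ANOVAs, text report
    from .sweep import compare_weight_levels

    report = []
    weight_cols = [c for c in rows.columns if c.startswith("w_")]
    for wc in weight_cols:
        for resp in ("response", "rho"):
            try:
                report.append(str(compare_weight_levels(rows, resp, wc)))
            except ValueError as exc:
                report.append(f"{resp} ~ {wc}: {exc}")
    p["anova"].write_text(
        "# selindex {} seed={} config={}\n\n".format(
            __version__, cfg.seed, cfg.hash()
        ) + "\n\n".join(report)
    )


def stage_select(cfg: PipelineConfig):
    p = _paths(cfg)
    best = read_table(p["best"])
    if best.empty:
        raise PipelineError("select", "no-weights",
                            "no economic weight satisfied the criteria")
    weight_cols = [c for c in best.columns if c.startswith("w_")]
    traits = [c[2:] for c in weight_cols]
    trial = read_trial(p["trial"], truth_path=p["truth"])
    datasets = trial.managements if cfg.management_specific_cp else ["combined"]

    records = []
    sets: list[SelectionSet] = []
    for label in datasets:
        C = read_matrix(_cp_paths(cfg, label)[0])
        P = read_matrix(_cp_paths(cfg, label)[1])
        blues = read_table(_blue_path(cfg, label), index_col=0)
        k = _intensity(cfg, len(blues))
        for _, row in best.iterrows():
            w = np.array([row[c] for c in weight_cols], float)
            for sname in cfg.scenarios:
                restriction = SCENARIO_ALIASES[sname]
                model = restricted_coefficients(P.values, C.values, w,
                                                restriction,
                                                trait_names=tuple(C.columns))
                scores = index_values(model, blues)
                sel = select_top_fraction(scores, cfg.fraction, dataset=label,
                                          scenario=restriction.label,
                                          weights=tuple(w))
                sets.append(sel)
                for g in sorted(sel.genotypes):
                    records.append(
                        {"genotype": g, "dataset": label,
                         "scenario": restriction.label,
                         **{c: row[c] for c in weight_cols}}
                    )
    write_table(pd.DataFrame(records), p["selections"], seed=cfg.seed,
                config_hash=cfg.hash())
    return sets


def stage_report(cfg: PipelineConfig):
    p = _paths(cfg)
    sel = read_table(p["selections"])
    weight_cols = [c for c in sel.columns if c.startswith("w_")]
    sets = []
    for (dataset, scenario, *wvals), grp in sel.groupby(
        ["dataset", "scenario"] + weight_cols
    ):
        sets.append(SelectionSet(genotypes=frozenset(grp["genotype"]),
                                 fraction=cfg.fraction, dataset=dataset,
                                 scenario=scenario, weights=tuple(wvals)))
    n_weights = sel[weight_cols].drop_duplicates().shape[0]
    min_w = cfg.min_weights if cfg.min_weights is not None else n_weights
    report = consistency_analysis(sets, min_weights=min_w,
                                  min_scenarios=cfg.min_scenarios)
    out = report.membership.copy()
    out["n_contexts"] = report.counts
    out["consensus"] = [int(g in report.consensus) for g in out.index]
    write_table(out, p["consistency"], seed=cfg.seed, config_hash=cfg.hash(),
                index=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "stages": list(STAGES),
        "n_selection_sets": len(sets),
        "n_consensus": len(report.consensus),
        "consensus": sorted(report.consensus),
    }
    p["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "estimate": stage_estimate,
    "sweep": stage_sweep,
    "best-weights": stage_best_weights,
    "select": stage_select,
    "report": stage_report,
}


def run_stage(cfg: PipelineConfig, stage: str):
    if stage not in _STAGE_FUNCS:
        raise PipelineError(stage, "unknown-stage",
                            f"choose from {list(_STAGE_FUNCS)}")
    try:
        return _STAGE_FUNCS[stage](cfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, type(exc).__name__, str(exc)) from exc


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages in order; returns the run directory."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(cfg.outdir / "run.log")
    logging.getLogger("selindex").addHandler(handler)
    try:
        for stage in STAGES:
            logger.info("stage %s", stage)
            run_stage(cfg, stage)
    finally:
        logging.getLogger("selindex").removeHandler(handler)
        handler.close()
    return cfg.outdir
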