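"""End-to-end experiment driver: multiple independent GA runs, metrics,
selection and reproducible on-disk outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from joblib import Parallel, delayed

from . import __version__
from .fitness import SaccadeTargetSet, nystagmus_objectives, saccade_objectives
from .integrate import SolverConfig
from .io import (
    read_cycle_csv,
    read_profile_csv,
    write_cycle_csv,
    write_front_csv,
    write_json,
    write_profile_csv,
)
from .metrics import aggregate_runs, hypervolume_indicator, min_front_distance, reference_point
from .model import Bounds, DEFAULT_BOUNDS, FREE_PARAMS, ModelParameters
from .nsga2 import GAConfig, NSGAResult, run_nsga2, select_best
from .upo import extract_upo

logger = logging.getLogger(__name__)

MODES = ("fit-nystagmus", "fit-saccades", "extract-upo", "make-synthetic", "metrics")


@dataclass(frozen=True)
class ExperimentConfig:
    mode: str
    output_dir: str
    target_paths: Tuple[str, ...] = ()
    bounds: Bounds = DEFAULT_BOUNDS
    ga: GAConfig = GAConfig()
    solver: SolverConfig = SolverConfig(rtol=1e-5, atol=1e-8)
    n_runs: int = 1
    seeds: Tuple[int, ...] = (0,)
    n_workers: int = 1
    selection_methods: Tuple[str, ...] = ("min_period", "min_norm")

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be unique")
        if len(self.seeds) < self.n_runs:
            raise ValueError("need one seed per run")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bounds"] = self.bounds.to_dict()
        return d


def _manifest(cfg: ExperimentConfig) -> dict:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "oculofit_version": __version__,
        "numpy_version": np.__version__,
    }


def _single_run(objective_fn, bounds, ga_cfg) -> NSGAResult:
    return run_nsga2(objective_fn, bounds, ga_cfg)


def run_ga_study(
    objective_fn,
    bounds: Bounds,
    ga: GAConfig,
    seeds: Sequence[int],
    n_workers: int = 1,
) -> List[NSGAResult]:
    """Independent NSGA-II runs, one per seed; results are ordered by seed
    and independent of the worker count."""
    cfgs = [ga.replace(seed=int(s)) for s in seeds]
    if n_workers <= 1 or len(cfgs) < 2:
        return [_single_run(objective_fn, bounds, c) for c in cfgs]
    return Parallel(n_jobs=n_workers)(
        delayed(_single_run)(objective_fn, bounds, c) for c in cfgs
    )


def summarise_runs(results: Sequence[NSGAResult]) -> dict:
    """Cross-run aggregates: hypervolume indicator, minimum front distance
    and per-parameter statistics of the min-norm individual, each reported
    as (mean, SD, CV)."""
    fronts = [r.front.objective_matrix for r in results]
    finite_fronts = [f for f in fronts if len(f)]
    y_r = reference_point(finite_fronts)
    h_i = [hypervolume_indicator(f, y_r) for f in finite_fronts]
    d_f = [min_front_distance(f) for f in finite_fronts]
    best = [select_best(r.front, "min_norm") for r in results]
    params = np.array([b.params for b in best])
    out = {
        "reference_point": [float(v) for v in y_r],
        "hypervolume_indicator": dict(
            zip(("mean", "sd", "cv"), aggregate_runs(h_i))
        ),
        "min_front_distance": dict(zip(("mean", "sd", "cv"), aggregate_runs(d_f))),
        "parameters_min_norm": {
            name: dict(zip(("mean", "sd", "cv"), aggregate_runs(params[:, i])))
            for i, name in enumerate(FREE_PARAMS)
        },
    }
    return out


def _write_fit_outputs(cfg, results, objective_names, out):
    for i, res in enumerate(results):
        write_front_csv(res.front, out / f"front_run{i}.csv", objective_names)
        rows = []
        for rec in res.history:
            rows.append(
                {
                    "generation": rec.generation,
                    "front_size": len(rec.front_objectives),
                    "min_front_distance": min_front_distance(rec.front_objectives)
                    if len(rec.front_objectives)
                    else np.nan,
                    "mutation_scale": rec.mutation_scale,
                    "n_evaluations": rec.n_evaluations,
                }
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / f"history_run{i}.csv", index=False)
    summary = summarise_runs(results)
    selected = {}
    for method in cfg.selection_methods:
        per_run = []
        for res in results:
            ind = select_best(res.front, method)
            per_run.append(
                {
                    "params": dict(zip(FREE_PARAMS, map(float, ind.params))),
                    "objectives": list(map(float, ind.objectives.components)),
                }
            )
        selected[method] = per_run
    write_json({"summary": summary, "selected": selected}, out / "summary.json")
    return summary


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute one experiment per its mode and write results under
    ``cfg.output_dir``; returns the summary dictionary."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(_manifest(cfg), out / "manifest.json")

    if cfg.mode == "fit-nystagmus":
        target = read_cycle_csv(cfg.target_paths[0])
        fn = lambda x: nystagmus_objectives(
            ModelParameters.from_free_array(x), target, cfg.solver
        )
        results = run_ga_study(fn, cfg.bounds, cfg.ga, cfg.seeds[: cfg.n_runs], cfg.n_workers)
        return _write_fit_outputs(cfg, results, ["d_S", "d_P"], out)

    if cfg.mode == "fit-saccades":
        targets = SaccadeTargetSet(
            tuple(read_profile_csv(p) for p in cfg.target_paths)
        )
        fn = lambda x: saccade_objectives(
            ModelParameters.from_free_array(x), targets, cfg.solver
        )
        results = run_ga_study(fn, cfg.bounds, cfg.ga, cfg.seeds[: cfg.n_runs], cfg.n_workers)
        names = [f"d_{j + 1}" for j in range(len(targets))]
        return _write_fit_outputs(cfg, results, names, out)

    if cfg.mode == "extract-upo":
        from .io import read_timeseries

        t, gaze, fs = read_timeseries(cfg.target_paths[0])
        upo = extract_upo(gaze, fs, source_id=str(cfg.target_paths[0]))
        write_cycle_csv(upo.cycle, out / "upo_cycle.csv")
        meta = {
            "tau_star_s": upo.tau_star,
            "period_s": upo.cycle.period,
            "source": upo.source_id,
        }
        write_json(meta, out / "upo_meta.json")
        return meta

    if cfg.mode == "make-synthetic":
        from .synthetic import (
            OSCILLATORY_PRESETS,
            SACCADE_PRESET,
            generate_nystagmus_target,
            generate_saccade_targets,
        )

        made = {"cycles": [], "profiles": []}
        for i, p in enumerate(OSCILLATORY_PRESETS):
            c = generate_nystagmus_target(p)
            path = out / f"target_cycle_{i}.csv"
            write_cycle_csv(c, path)
            made["cycles"].append(str(path))
        for prof in generate_saccade_targets(SACCADE_PRESET).profiles:
            path = out / f"target_saccade_{int(prof.amplitude)}deg.csv"
            write_profile_csv(prof, path)
            made["profiles"].append(str(path))
        write_json(made, out / "synthetic_manifest.json")
        return made

    # metrics mode: recompute front metrics from stored front CSVs
    from .io import read_front_csv

    fronts = [read_front_csv(p)[1] for p in cfg.target_paths]
    y_r = reference_point(fronts)
    per_run = {
        str(p): {
            "hypervolume_indicator": hypervolume_indicator(f, y_r),
            "min_front_distance": min_front_distance(f),
        }
        for p, f in zip(cfg.target_paths, fronts)
    }
    result = {"reference_point": [float(v) for v in y_r], "runs": per_run}
    write_json(result, out / "metrics.json")
    return result
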