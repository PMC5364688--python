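"""CSV/JSON/YAML input-output helpers.

Time series travel as two-column CSV (time plus value); cycles carry
their period in a ``# key=value`` header comment; Pareto fronts are CSV
tables of free parameters plus objectives.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitness import SaccadeProfile
from .model import FREE_PARAMS
from .nsga2 import ParetoFrontEstimate
from .waveform import Cycle

__all__ = [
    "read_timeseries",
    "write_cycle_csv",
    "read_cycle_csv",
    "write_profile_csv",
    "read_profile_csv",
    "write_front_csv",
    "read_front_csv",
]


def _read_commented_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_timeseries(
    path,
    columns: Tuple[str, str] = ("time_s", "gaze_deg"),
    uniformity_tol: float = 0.01,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Read a (time, value) CSV; returns (times, values, sampling rate).

    The rate is inferred from the median spacing; spacing deviating from
    it by more than `uniformity_tol` (fractional), or a non-monotone time
    column, is an error.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}")
    t = df[columns[0]].to_numpy(dtype=float)
    x = df[columns[1]].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > uniformity_tol * med):
        raise ValueError("time column is not uniformly sampled")
    return t, x, 1.0 / med


def write_cycle_csv(cycle: Cycle, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# period_s={cycle.period!r}\n")
        fh.write(f"# sample_interval_s={cycle.sample_interval!r}\n")
        pd.DataFrame({"time_s": cycle.times, "gaze_deg": cycle.values}).to_csv(
            fh, index=False, float_format="%.17g"
        )


def read_cycle_csv(path) -> Cycle:
    meta = _read_commented_header(path)
    t, x, _ = read_timeseries(path)
    period = float(meta.get("period_s", t[-1]))
    interval = float(meta.get("sample_interval_s", t[1] - t[0]))
    return Cycle(times=t, values=x, period=period, sample_interval=interval)


def write_profile_csv(profile: SaccadeProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# amplitude_deg={profile.amplitude!r}\n")
        pd.DataFrame(
            {"time_s": profile.times, "velocity_deg_s": profile.velocities}
        ).to_csv(fh, index=False, float_format="%.17g")


def read_profile_csv(path) -> SaccadeProfile:
    meta = _read_commented_header(path)
    t, v, _ = read_timeseries(path, columns=("time_s", "velocity_deg_s"))
    return SaccadeProfile(amplitude=float(meta["amplitude_deg"]), times=t, velocities=v)


def write_front_csv(front: ParetoFrontEstimate, path, objective_names: Optional[Sequence[str]] = None) -> None:
    X = front.decision_matrix
    F = front.objective_matrix
    if objective_names is None:
        objective_names = [f"objective_{j + 1}" for j in range(F.shape[1])]
    cols = {k: X[:, i] for i, k in enumerate(FREE_PARAMS)}
    cols.update({name: F[:, j] for j, name in enumerate(objective_names)})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_front_csv(path) -> Tuple[np.ndarray, np.ndarray]:
    """Returns (decision matrix, objective matrix)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    X = df[list(FREE_PARAMS)].to_numpy(dtype=float)
    obj_cols = [c for c in df.columns if c not in FREE_PARAMS]
    return X, df[obj_cols].to_numpy(dtype=float)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
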