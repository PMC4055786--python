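"""Delimited-text input/output and the synthetic-fixture generator.

Tables are plain CSV (comma, decimal point, UTF-8, mandatory header on
output).  Observation files may or may not carry a header row; columns are
addressed by 1-based index, mirroring the import dialog of interactive
tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SolverConfig, Trajectory, integrate
from .fitting import Observations
from .models import Model

__all__ = [
    "read_observations",
    "write_observations",
    "write_trajectory_table",
    "generate_pk_dataset",
    "write_metadata",
]


def read_observations(path, x_col: int = 1, y_col: int = 2,
                      delimiter: str = ",") -> Observations:
    """Read (time, value) records from a delimited text file.

    ``x_col`` and ``y_col`` are 1-based column indices.  A first row that is
    not numeric in the selected columns is treated as a header.  Non-numeric
    data cells are rejected with the offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path, header=None, sep=delimiter, skip_blank_lines=True,
                     comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: file contains no data")
    for col, label in ((x_col, "x_col"), (y_col, "y_col")):
        if not (1 <= col <= df.shape[1]):
            raise ValueError(
                f"{path}: {label}={col} out of range; file has {df.shape[1]} column(s)")
    sub = df.iloc[:, [x_col - 1, y_col - 1]]

    first_numeric = pd.to_numeric(sub.iloc[0], errors="coerce").notna().all()
    offset = 0 if first_numeric else 1
    body = sub.iloc[offset:]
    if body.empty:
        raise ValueError(f"{path}: no data rows below the header")
    parsed = body.apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna() & body.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0]) + offset + 1
        raise ValueError(f"{path}: non-numeric value in row {row}")
    if parsed.isna().to_numpy().any():
        row = int(np.argwhere(parsed.isna().to_numpy())[0][0]) + offset + 1
        raise ValueError(f"{path}: missing value in row {row}")
    # final conversion via float() for correctly rounded full-precision parsing
    return Observations(times=body.iloc[:, 0].astype(float).to_numpy(),
                        values=body.iloc[:, 1].astype(float).to_numpy())


def write_observations(obs: Observations, path) -> None:
    """Write observations as CSV with a header row, full precision."""
    df = obs.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def write_trajectory_table(trajectory: Trajectory, path) -> None:
    """Write a trajectory as CSV: `time` first, one column per series.

    Output is bit-stable for fixed inputs and seed.
    """
    trajectory.to_frame().to_csv(path, index=False, float_format="%.17g")


def generate_pk_dataset(model: Model, regimen, config: SolverConfig,
                        sample_times, noise_sd: float = 0.0, seed=None,
                        series: str = "conc") -> Observations:
    """Simulate the model and sample noisy observations at given times.

    Observations are ``predicted * exp(N(0, noise_sd))`` — the multiplicative
    lognormal residual conventional for concentration data — and are
    reproducible under ``seed``.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if np.any(sample_times < config.start_time) or np.any(sample_times > config.stop_time):
        raise ValueError("sample_times must lie within the simulation window")
    traj = integrate(model, regimen, config)
    pred = np.interp(sample_times, traj.times, traj[series])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pred = pred * np.exp(rng.normal(0.0, noise_sd, size=pred.shape))
    return Observations(times=sample_times, values=pred)


def write_metadata(path, *, config: dict | None, seed, command: str) -> None:
    """Sidecar JSON recording everything needed to reproduce a run."""
    from . import __version__

    payload = {
        "pmxsim_version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
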