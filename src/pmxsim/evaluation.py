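"""Programmatic equivalents of interactive analyses: statistic-at-time
extraction, parameter sweeps, and summary statistics with normal-theory
intervals.

Instead of the sentinel trick used interactively (setting the statistic to
+/-Inf away from the evaluation time and taking a max/min afterwards), the
value is read directly at the first output time within one step of the
requested time; a missing match is reported explicitly as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .engine import DoseRegimen, SolverConfig, integrate
from .models import Model

__all__ = [
    "SweepSpec",
    "SummaryStats",
    "statistic_at_time",
    "parameter_sweep",
    "array_summary",
]

#: default interval multiplier: the 97.5th percentile of the standard normal
#: (1.96 at two decimals), computed rather than hard-coded
DEFAULT_Z = float(norm.ppf(0.975))

_STATS = ("min", "max", "mean", "at_time")


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep: vary ``parameter`` over an even grid and record a
    summary statistic of each requested output series per grid value.

    ``steps = n`` yields the grid ``start + k*(stop-start)/(n-1)`` (a single
    point when ``n = 1``); e.g. 11 steps from 100 to 200 give
    100, 110, ..., 200.  ``statistic`` is ``min``, ``max``, ``mean`` over all
    output times, or ``at_time`` (requires ``at_time``/``window``).
    """

    parameter: str
    start: float
    stop: float
    steps: int
    outputs: tuple[str, ...]
    statistic: str = "max"
    at_time: float | None = None
    window: float | None = None

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.statistic not in _STATS:
            raise ValueError(f"statistic must be one of {_STATS}")
        if self.statistic == "at_time" and self.at_time is None:
            raise ValueError("at_time statistic requires an at_time value")
        object.__setattr__(self, "outputs", tuple(self.outputs))

    @property
    def grid(self) -> np.ndarray:
        if self.steps == 1:
            return np.array([float(self.start)])
        return self.start + np.arange(self.steps) * (
            (self.stop - self.start) / (self.steps - 1))


@dataclass(frozen=True)
class SummaryStats:
    """Mean, SD (population denominator) and a mean +/- z*sd interval."""

    m: float
    sd: float
    int_low: float
    int_high: float
    z: float


def statistic_at_time(times, values, eval_time: float, dt: float):
    """Value of a series at the first grid time ``t`` with ``|t - eval_time| < dt``.

    Returns ``None`` when no output time matches — the explicit missing
    marker, in place of an infinity sentinel.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("series is empty")
    hits = np.nonzero(np.abs(times - eval_time) < dt)[0]
    if hits.size == 0:
        return None
    return np.asarray(values)[hits[0]]


def parameter_sweep(model: Model, regimen: DoseRegimen | None,
                    config: SolverConfig, spec: SweepSpec,
                    seed=None) -> pd.DataFrame:
    """One full simulation per grid value of the swept parameter.

    The parameter may be a structural model parameter or a dose-regimen field
    (``dose`` is an alias for the regimen ``amount``).  Returns a tidy table
    with the parameter value and the requested statistic per output series.
    """
    name = spec.parameter
    in_model = name in model.params
    reg_field = {"dose": "amount"}.get(name, name)
    in_regimen = regimen is not None and hasattr(regimen, reg_field)
    if not in_model and not in_regimen:
        raise KeyError(
            f"parameter {name!r} is neither a model parameter "
            f"({sorted(model.params)}) nor a regimen field")

    window = spec.window if spec.window is not None else (
        config.dt_out if config.dt_out > 0 else config.dt)
    rows = []
    for value in spec.grid:
        m = model.with_params(**{name: float(value)}) if in_model else model
        r = regimen
        if not in_model:
            r = dc_replace(regimen, **{reg_field: float(value)})
        traj = integrate(m, r, config)
        row: dict = {name: float(value)}
        for out in spec.outputs:
            series = traj[out]
            if spec.statistic == "min":
                row[out] = float(np.min(series))
            elif spec.statistic == "max":
                row[out] = float(np.max(series))
            elif spec.statistic == "mean":
                row[out] = float(np.mean(series))
            else:
                val = statistic_at_time(traj.times, series, spec.at_time, window)
                row[out] = None if val is None else float(val)
        rows.append(row)
    return pd.DataFrame(rows)


def array_summary(values, z: float | None = None) -> SummaryStats:
    """Mean, population SD and the ``m +/- z*sd`` normal-theory interval.

    ``z`` defaults to the 97.5th standard-normal percentile so that the
    interval estimates a 95% range.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty array")
    if z is None:
        z = DEFAULT_Z
    m = float(np.mean(values))
    sd = float(np.std(values))  # population denominator n
    return SummaryStats(m=m, sd=sd, int_low=m - z * sd, int_high=m + z * sd, z=z)
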