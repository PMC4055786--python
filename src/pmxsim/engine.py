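"""Numerical integration of compartmental systems with exact dosing events.

The engine solves a compartmental ODE system on a time grid and superimposes
drug administration on top of it:

* **bolus doses** are discrete state increments of ``amount x bioavailability``
  applied at the first grid point at or after the scheduled time (doses that
  fall between grid points are snapped forward and a warning is logged);
* **zero-order infusions** enter the right-hand side as a rate term that is
  switched on inside periodic infusion windows.

Fixed-step methods (Euler, midpoint RK2, classical RK4) are implemented
directly; the ``adaptive_stiff`` method delegates to a variable-step implicit
solver (LSODA) that honours ``tolerance``, ``dt_min`` and ``dt_max`` and is
restarted at every bolus time so that the discontinuity never falls inside an
accepted step.

States may be scalar per compartment or arrays over subjects/arms: the state
vector has shape ``(n_states,)`` or ``(n_states, n_subjects)`` and model
parameters broadcast against the trailing axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SolverConfig",
    "DoseRegimen",
    "Trajectory",
    "IntegrationError",
    "step",
    "integrate",
    "dose_times",
    "infusion_rate",
    "saturable_absorption_rate",
]

log = logging.getLogger(__name__)

FIXED_STEP_METHODS = ("euler", "rk2", "rk4")
METHODS = FIXED_STEP_METHODS + ("adaptive_stiff",)

_ROUTE_ALIASES = {
    "bolus": "bolus_to_compartment",
    "bolus_to_compartment": "bolus_to_compartment",
    "infusion": "zero_order_infusion",
    "zero_order_infusion": "zero_order_infusion",
}


class IntegrationError(RuntimeError):
    """Raised when the ODE solver produces non-finite state or fails."""


@dataclass(frozen=True)
class SolverConfig:
    """Integration method, time window and step/tolerance controls.

    Parameters
    ----------
    method:
        One of ``euler``, ``rk2``, ``rk4`` (fixed step, controlled by ``dt``)
        or ``adaptive_stiff`` (variable step, controlled by ``tolerance``,
        ``dt_min`` and ``dt_max``).
    start_time, stop_time:
        Integration window. It is good practice to start at least one step
        before the first dose; the default start is -1 time unit.
    dt_out:
        Output interval. ``0`` returns every accepted step; a positive value
        returns an evenly spaced output grid.
    """

    start_time: float = -1.0
    stop_time: float = 100.0
    method: str = "rk4"
    dt: float = 0.02
    dt_min: float = 1e-6
    dt_max: float = 0.1
    tolerance: float = 1e-6
    dt_out: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if not self.start_time < self.stop_time:
            raise ValueError(
                f"start_time ({self.start_time}) must be < stop_time ({self.stop_time})"
            )
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.dt_min > self.dt_max:
            raise ValueError("dt_min must be <= dt_max")
        if self.dt_out < 0:
            raise ValueError("dt_out must be >= 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class DoseRegimen:
    """One administration pattern.

    ``amount`` and ``bioavailability`` may be scalars or per-subject arrays.
    ``n_doses = 0`` means unlimited dosing within the simulation window.
    For infusions, ``infusion_rate`` (mass/time) runs for ``infusion_duration``
    within each ``interval``.
    """

    amount: float | np.ndarray = 0.0
    route: str = "bolus"
    first_time: float = 0.0
    interval: float = 24.0
    n_doses: int = 0
    lag: float = 0.0
    infusion_rate: float | np.ndarray = 0.0
    infusion_duration: float = 0.0
    bioavailability: float | np.ndarray = 1.0
    target: str | None = None

    def __post_init__(self) -> None:
        if self.route not in _ROUTE_ALIASES:
            raise ValueError(f"unknown route {self.route!r}")
        object.__setattr__(self, "route", _ROUTE_ALIASES[self.route])
        if np.any(np.asarray(self.amount) < 0):
            raise ValueError("amount must be >= 0")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.n_doses < 0:
            raise ValueError("n_doses must be >= 0")
        if self.infusion_duration < 0:
            raise ValueError("infusion_duration must be >= 0")
        if self.infusion_duration > self.interval:
            raise ValueError("infusion_duration must be <= interval")
        f = np.asarray(self.bioavailability)
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("bioavailability must lie in [0, 1]")


@dataclass
class Trajectory:
    """Time grid plus named state and derived-output series.

    Each series has shape ``(n_times,)`` for a single subject or
    ``(n_times, n_subjects)`` for array models.
    """

    times: np.ndarray
    states: dict[str, np.ndarray]
    outputs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, series in {**self.states, **self.outputs}.items():
            if series.shape[0] != self.times.shape[0]:
                raise ValueError(f"series {name!r} length does not match times")

    @property
    def series(self) -> dict[str, np.ndarray]:
        return {**self.states, **self.outputs}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a table: `time` first, one column per series.

        Array series are expanded with 1-based subject suffixes
        (``central_1``, ``central_2``, ...), mirroring array notation.
        """
        cols: dict[str, np.ndarray] = {"time": self.times}
        for name, series in self.series.items():
            if series.ndim == 1:
                cols[name] = series
            else:
                flat = series.reshape(series.shape[0], -1)
                for j in range(flat.shape[1]):
                    cols[f"{name}_{j + 1}"] = flat[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dosing helpers


def dose_times(regimen: DoseRegimen, config: SolverConfig) -> list[tuple[float, float | np.ndarray]]:
    """Scheduled bolus times and delivered amounts within the window.

    Times are ``first_time + lag + k*interval`` for ``k = 0..n_doses-1``
    (unlimited if ``n_doses = 0``), intersected with
    ``[start_time, stop_time]``; each carries ``amount x bioavailability``.
    """
    eps = 1e-9 * max(1.0, abs(config.stop_time))
    delivered = np.asarray(regimen.amount, dtype=float) * np.asarray(
        regimen.bioavailability, dtype=float
    )
    if delivered.ndim == 0:
        delivered = float(delivered)
    out: list[tuple[float, float | np.ndarray]] = []
    t0 = regimen.first_time + regimen.lag
    k = 0
    while True:
        if regimen.n_doses and k >= regimen.n_doses:
            break
        t = t0 + k * regimen.interval
        if t > config.stop_time + eps:
            break
        if t >= config.start_time - eps:
            out.append((t, delivered))
        k += 1
    return out


def infusion_rate(t: float, rate: float, duration: float, freq: float) -> float:
    """Zero-order infusion rate at time ``t``.

    Returns ``rate`` if ``t >= 0`` and ``t mod freq < duration``, else 0 —
    the modulo-window formulation of a periodic constant-rate infusion.
    """
    if duration < 0 or freq <= 0:
        raise ValueError("duration must be >= 0 and freq > 0")
    if t < 0:
        return 0.0
    return rate if math.fmod(t, freq) < duration else 0.0


def saturable_absorption_rate(depot_amount, ka, absmax):
    """Capped first-order absorption: ``min(absmax, ka * depot_amount)``."""
    return np.minimum(absmax, ka * np.asarray(depot_amount, dtype=float))


# ---------------------------------------------------------------------------
# Stepping


def step(method: str, rhs: Callable, t: float, state: np.ndarray, dt: float) -> np.ndarray:
    """Advance the state by one fixed step of the named method.

    ``rhs(t, y)`` must return the derivative array; ``method`` is one of
    ``euler``, ``rk2`` (midpoint) or ``rk4`` (classical).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    y = np.asarray(state, dtype=float)
    if method == "euler":
        return y + dt * _checked_rhs(rhs, t, y)
    if method == "rk2":
        k1 = _checked_rhs(rhs, t, y)
        k2 = _checked_rhs(rhs, t + dt / 2.0, y + dt / 2.0 * k1)
        return y + dt * k2
    if method == "rk4":
        k1 = _checked_rhs(rhs, t, y)
        k2 = _checked_rhs(rhs, t + dt / 2.0, y + dt / 2.0 * k1)
        k3 = _checked_rhs(rhs, t + dt / 2.0, y + dt / 2.0 * k2)
        k4 = _checked_rhs(rhs, t + dt, y + dt * k3)
        return y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    raise ValueError(f"unknown fixed-step method {method!r}")


def _checked_rhs(rhs: Callable, t: float, y: np.ndarray) -> np.ndarray:
    dy = np.asarray(rhs(t, y), dtype=float)
    if not np.all(np.isfinite(dy)):
        bad = np.argwhere(~np.isfinite(dy))
        raise IntegrationError(
            f"non-finite derivative at t={t:g} for state index {tuple(bad[0])}"
        )
    return dy


# ---------------------------------------------------------------------------
# Full integration


def integrate(model, regimens: Sequence[DoseRegimen] | DoseRegimen | None,
              config: SolverConfig, init_state: dict | None = None) -> Trajectory:
    """Integrate ``model`` over the configured window with dosing events.

    Parameters
    ----------
    model:
        A :class:`pmxsim.models.Model` (anything with ``state_names``,
        ``rhs(t, y, u)``, ``init`` and optional ``outputs``).
    regimens:
        Dose regimens; bolus regimens become state increments, infusion
        regimens rate inputs ``u``.
    init_state:
        Overrides for initial amounts per state name; values may be
        per-subject arrays to simulate many subjects at once.  Per-subject
        model parameters require a per-subject initial state (or regimen
        amount) so that the state carries the subject axis.
    """
    if regimens is None:
        regimens = []
    elif isinstance(regimens, DoseRegimen):
        regimens = [regimens]
    names = list(model.state_names)
    index = {n: i for i, n in enumerate(names)}

    init = dict(getattr(model, "init", {}) or {})
    if init_state:
        init.update(init_state)

    shapes = [np.shape(np.asarray(init.get(n, 0.0))) for n in names]
    for reg in regimens:
        shapes.append(np.shape(np.asarray(reg.amount)))
        shapes.append(np.shape(np.asarray(reg.bioavailability)))
        shapes.append(np.shape(np.asarray(reg.infusion_rate)))
    subject_shape = np.broadcast_shapes(*shapes)
    y0 = np.stack(
        [np.broadcast_to(np.asarray(init.get(n, 0.0), dtype=float), subject_shape)
         for n in names]
    ).astype(float)

    bolus: list[tuple[float, int, np.ndarray | float]] = []
    infusions: list[tuple[int, DoseRegimen]] = []
    for reg in regimens:
        tgt = reg.target if reg.target is not None else names[0]
        if tgt not in index:
            raise KeyError(f"unknown target compartment {tgt!r}; states are {names}")
        if reg.route == "bolus_to_compartment":
            for t, amt in dose_times(reg, config):
                bolus.append((t, index[tgt], amt))
        else:
            infusions.append((index[tgt], reg))

    u_zero = np.zeros_like(y0)
    u_zero.setflags(write=False)

    def u_of(t: float) -> np.ndarray:
        if not infusions:
            return u_zero
        u = np.zeros_like(y0)
        for idx, reg in infusions:
            t0 = reg.first_time + reg.lag
            rel = t - t0
            if rel < 0:
                continue
            if reg.n_doses and rel >= reg.n_doses * reg.interval:
                continue
            if math.fmod(rel, reg.interval) < reg.infusion_duration:
                u[idx] += np.asarray(reg.infusion_rate, dtype=float)
        return u

    if config.method in FIXED_STEP_METHODS:
        times, ys = _integrate_fixed(model.rhs, u_of, y0, bolus, config, names)
    else:
        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            return model.rhs(t, y, u_of(t))

        times, ys = _integrate_adaptive(rhs, y0, bolus, config, names)

    states = {n: ys[:, i, ...] for i, n in enumerate(names)}
    outputs = {}
    if getattr(model, "outputs", None) is not None:
        outputs = model.outputs(times, states)
    return Trajectory(times=times, states=states, outputs=outputs)


def _integrate_fixed(model_rhs, u_of, y0, bolus, config, names):
    start, stop, dt = config.start_time, config.stop_time, config.dt
    n_steps = int(math.floor((stop - start) / dt + 1e-9))
    times = start + np.arange(n_steps + 1) * dt
    if times[-1] < stop - 1e-9 * dt:
        times = np.append(times, stop)

    tol = 1e-9 * max(dt, 1.0)
    events: dict[int, list[tuple[int, np.ndarray | float]]] = {}
    for t_dose, idx, amt in bolus:
        k = int(np.searchsorted(times, t_dose - tol, side="left"))
        if k >= len(times):
            continue
        if abs(times[k] - t_dose) > tol:
            log.warning(
                "dose at t=%g snapped forward to grid time t=%g", t_dose, times[k]
            )
        events.setdefault(k, []).append((idx, amt))

    ys = np.empty((len(times),) + y0.shape)
    y = y0.copy()
    for k, t in enumerate(times):
        for idx, amt in events.get(k, ()):
            y[idx] = y[idx] + amt
        ys[k] = y
        if k + 1 < len(times):
            h = times[k + 1] - t
            # the zero-order input is held constant over the step (sampled at
            # the step start) so piecewise-constant infusion windows aligned
            # with the grid deliver their mass exactly
            u_k = u_of(t)
            y = step(config.method, lambda tt, yy: model_rhs(tt, yy, u_k), t, y, h)
            if not np.all(np.isfinite(y)):
                bad = int(np.argwhere(~np.isfinite(y))[0][0])
                raise IntegrationError(
                    f"non-finite state {names[bad]!r} after step at t={t:g}"
                )

    if config.dt_out > 0:
        times, ys = _resample(times, ys, config)
    return times, ys


def _integrate_adaptive(rhs, y0, bolus, config, names):
    from scipy.integrate import solve_ivp

    shape = y0.shape

    def f(t, y_flat):
        return np.asarray(rhs(t, y_flat.reshape(shape)), dtype=float).ravel()

    # segment boundaries: start, unique dose times, stop
    eps = 1e-12 * max(1.0, abs(config.stop_time))
    cuts = sorted({config.start_time, config.stop_time}
                  | {t for t, _, _ in bolus
                     if config.start_time <= t <= config.stop_time})
    doses_at: dict[float, list] = {}
    for t, idx, amt in bolus:
        doses_at.setdefault(t, []).append((idx, amt))

    y = y0.copy().ravel()
    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    dense = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        for idx, amt in doses_at.get(a, ()):
            yr = y.reshape(shape)
            yr[idx] = yr[idx] + amt
            y = yr.ravel()
        sol = solve_ivp(
            f, (a, b), y, method="LSODA",
            rtol=config.tolerance, atol=config.tolerance * 1e-3,
            max_step=config.dt_max, min_step=config.dt_min,
            dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(
                f"adaptive solver failed on [{a:g}, {b:g}]: {sol.message}"
            )
        all_t.append(sol.t)
        all_y.append(sol.y.T.reshape((-1,) + shape))
        dense.append((a, b, sol.sol))
        y = sol.y[:, -1].copy()
    for idx, amt in doses_at.get(cuts[-1], ()):  # dose exactly at stop_time
        yr = y.reshape(shape)
        yr[idx] = yr[idx] + amt
        all_y[-1][-1] = yr
        y = yr.ravel()

    if config.dt_out > 0:
        n_out = int(math.floor((config.stop_time - config.start_time) / config.dt_out + 1e-9))
        times = config.start_time + np.arange(n_out + 1) * config.dt_out
        if times[-1] < config.stop_time - eps:
            times = np.append(times, config.stop_time)
        ys = np.empty((len(times),) + shape)
        seg = 0
        for j, t in enumerate(times):
            while seg + 1 < len(dense) and t > dense[seg][1]:
                seg += 1
            a, b, interp = dense[seg]
            ys[j] = interp(min(max(t, a), b)).reshape(shape)
        # replace samples at dose times with the post-dose value
        tol = 1e-9 * max(1.0, abs(config.stop_time))
        for t_dose in doses_at:
            hits = np.nonzero(np.abs(times - t_dose) < tol)[0]
            if hits.size == 0:
                continue
            if abs(t_dose - cuts[-1]) < tol:
                post = all_y[-1][-1]
            else:
                k = next(i for i, (a, _, _) in enumerate(dense) if abs(a - t_dose) < tol)
                post = all_y[k][0]
            for j in hits:
                ys[j] = post
        return times, ys

    # every accepted step; drop duplicated times at segment joins, keeping the
    # post-dose sample from the later segment
    times = all_t[0]
    ys = all_y[0]
    for t_seg, y_seg in zip(all_t[1:], all_y[1:]):
        keep = times < t_seg[0] - eps
        times = np.concatenate([times[keep], t_seg])
        ys = np.concatenate([ys[keep], y_seg])
    return times, ys


def _resample(times, ys, config):
    """Even output grid for fixed-step runs: subset when aligned, else interpolate."""
    ratio = config.dt_out / config.dt
    n_out = int(math.floor((config.stop_time - config.start_time) / config.dt_out + 1e-9))
    out_times = config.start_time + np.arange(n_out + 1) * config.dt_out
    if abs(ratio - round(ratio)) < 1e-9:
        r = int(round(ratio))
        idx = np.arange(0, len(times), r)
        if idx[-1] != len(times) - 1:
            idx = np.append(idx, len(times) - 1)
        return times[idx], ys[idx]
    flat = ys.reshape(ys.shape[0], -1)
    out = np.empty((len(out_times), flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(out_times, times, flat[:, j])
    return out_times, out.reshape((len(out_times),) + ys.shape[1:])
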