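"""Simple least-squares fitting of structural models to time-value data.

The fit minimizes the unweighted residual sum of squares between observed
values and model predictions (trajectory output linearly interpolated at the
observation times), treating every record as independent.  This deliberately
ignores any grouping of observations into subjects, so the estimates are
best used as starting values for a proper mixed-effects analysis; they are
not population estimates.

The optimizer is a derivative-free local search (Nelder-Mead) started from
each provided guess; with several starts per parameter the best local
optimum found is returned.  Known caveat: absorption/elimination rate pairs
in flip-flop kinetics are only locally identifiable — no automatic
reparameterization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .engine import DoseRegimen, SolverConfig, integrate
from .models import Model

__all__ = ["Observations", "FitResult", "least_squares_fit", "predict_at"]


@dataclass(frozen=True)
class Observations:
    """Observed (time, value) records; the optional subject labels are
    carried along but ignored by the fit."""

    times: np.ndarray
    values: np.ndarray
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if not np.all(np.isfinite(t)):
            raise ValueError("observation times must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times, "value": self.values}
        if self.subjects is not None:
            cols["subject"] = self.subjects
        return pd.DataFrame(cols)


@dataclass
class FitResult:
    """Estimates, residual sum of squares and convergence diagnostics."""

    estimates: dict[str, float]
    rss: float
    converged: bool
    n_iter: int
    n_starts: int = 1


def predict_at(model: Model, regimen, config: SolverConfig,
               times: np.ndarray, series: str = "conc") -> np.ndarray:
    """Model predictions at arbitrary times by linear interpolation of the
    simulated trajectory output grid."""
    traj = integrate(model, regimen, config)
    return np.interp(np.asarray(times, dtype=float), traj.times, traj[series])


def least_squares_fit(model: Model, regimen, config: SolverConfig,
                      data: Observations,
                      fit_params: Mapping[str, float | Sequence[float]],
                      series: str = "conc", seed=None,
                      max_iter: int = 2000) -> FitResult:
    """Least-squares fit of selected model parameters to observed data.

    ``fit_params`` maps parameter names to a starting value or a sequence of
    starting values (two guesses are customary); with multiple guesses the
    search is restarted from each assembled start vector and the best result
    kept.  Non-convergence is flagged on the result, with the best-found
    estimates, rather than raised.
    """
    if len(fit_params) == 0:
        raise ValueError("fit_params must name at least one parameter")
    if len(data) < 2:
        raise ValueError("need at least 2 observations to fit")
    names = list(fit_params)
    for p in names:
        if p not in model.params:
            raise KeyError(f"parameter {p!r} not in model {model.name!r}")

    guesses = {}
    for p, g in fit_params.items():
        g = np.atleast_1d(np.asarray(g, dtype=float))
        guesses[p] = g
    n_starts = max(len(g) for g in guesses.values())
    starts = [
        np.array([guesses[p][min(k, len(guesses[p]) - 1)] for p in names])
        for k in range(n_starts)
    ]

    # order of records must not matter: the objective is a plain sum
    def objective(x: np.ndarray) -> float:
        try:
            m = model.with_params(**dict(zip(names, x)))
            pred = predict_at(m, regimen, config, data.times, series)
        except (ValueError, FloatingPointError, OverflowError):
            return np.inf
        if not np.all(np.isfinite(pred)):
            return np.inf
        return float(np.sum((data.values - pred) ** 2))

    best = None
    total_iter = 0
    any_converged = False
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": max_iter, "maxfev": max_iter})
        total_iter += int(res.nit)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    return FitResult(
        estimates={p: float(v) for p, v in zip(names, best.x)},
        rss=float(best.fun),
        converged=bool(any_converged and np.isfinite(best.fun)),
        n_iter=total_iter,
        n_starts=n_starts,
    )
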