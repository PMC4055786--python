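"""Per-subject parameter generation: lognormal random effects, correlated
effects via Cholesky factorization, body-weight covariates, and the empirical
covariance check.

Individual parameters follow the usual lognormal convention
``p_i = p_pop * exp(eta_i)`` with ``eta ~ N(0, COV)``.  Correlated etas are
obtained as ``r @ CH`` where ``r`` is a block of independent standard normals
and ``CH`` is the upper-triangular Cholesky factor with ``CH.T @ CH = COV``.
A Monte-Carlo switch ``mc_switch`` set to 0 collapses every subject onto the
population-typical value while leaving the calculation structure intact.

The standard-normal block is drawn row-major (one row per subject) from a
single seeded stream, so enlarging the population appends subjects without
reshuffling the draws of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RandomEffectSpec",
    "PopulationSample",
    "cholesky_upper",
    "sample_mvn_effects",
    "sample_subject_params",
    "empirical_covariance",
    "sample_bodyweight",
]


@dataclass(frozen=True)
class RandomEffectSpec:
    """Specification of between-subject random effects.

    Either ``sds`` (independent effects, one sd per name) or ``cov`` (a full
    positive-definite covariance matrix in the order of ``names``) must be
    given.  ``mc_switch`` in {0, 1} multiplies every eta, switching
    variability off (0) or on (1).
    """

    names: tuple[str, ...]
    sds: tuple[float, ...] | None = None
    cov: np.ndarray | None = None
    mc_switch: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if (self.sds is None) == (self.cov is None):
            raise ValueError("give exactly one of sds or cov")
        if self.mc_switch not in (0, 1):
            raise ValueError("mc_switch must be 0 or 1")
        if self.sds is not None:
            sds = tuple(float(s) for s in self.sds)
            if len(sds) != len(self.names):
                raise ValueError("one sd per effect name required")
            if any(s < 0 for s in sds):
                raise ValueError("sds must be >= 0")
            object.__setattr__(self, "sds", sds)
        else:
            cov = np.asarray(self.cov, dtype=float)
            if cov.shape != (len(self.names),) * 2:
                raise ValueError("cov must be square with one row per effect name")
            if not np.allclose(cov, cov.T, atol=1e-12):
                raise ValueError("cov must be symmetric")
            object.__setattr__(self, "cov", cov)


class PopulationSample(pd.DataFrame):
    """Frozen per-subject parameter table: one row per subject, columns for
    individual parameter values and the raw etas (``eta_<name>``)."""

    @property
    def _constructor(self):
        return PopulationSample


def cholesky_upper(cov: np.ndarray) -> np.ndarray:
    """Upper-triangular factor ``CH`` with ``CH.T @ CH = cov``.

    Raises ``ValueError`` naming the first non-positive leading principal
    minor if ``cov`` is not positive definite.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("cov must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
        raise ValueError("cov must be symmetric")
    try:
        lower = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        for k in range(1, cov.shape[0] + 1):
            if np.linalg.det(cov[:k, :k]) <= 0:
                raise ValueError(
                    f"covariance matrix is not positive definite: leading "
                    f"principal minor of order {k} is non-positive"
                ) from None
        raise
    return lower.T


def sample_mvn_effects(n: int, cov: np.ndarray, seed=None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """``n`` independent multivariate-normal eta vectors with covariance ``cov``.

    Rows are ``r @ CH`` with ``r`` standard normal; the all-zero covariance is
    handled as the degenerate no-variability case.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cov = np.asarray(cov, dtype=float)
    m = cov.shape[0]
    if not np.any(cov):
        return np.zeros((n, m))
    ch = cholesky_upper(cov)
    if rng is None:
        rng = np.random.default_rng(seed)
    r = rng.standard_normal((n, m))
    return r @ ch


def sample_subject_params(pop_values: Mapping[str, float], spec: RandomEffectSpec,
                          n: int, seed=None,
                          rng: np.random.Generator | None = None) -> PopulationSample:
    """Sample a frozen per-subject parameter table.

    ``p_i = p_pop * exp(eta_i * mc_switch)``; with ``mc_switch = 0`` all
    subjects equal the population-typical subject.
    """
    for name in spec.names:
        if name not in pop_values:
            raise KeyError(f"no population value for effect {name!r}")
        if pop_values[name] <= 0:
            raise ValueError(f"population value for {name!r} must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = len(spec.names)
    if spec.cov is not None:
        etas = sample_mvn_effects(n, spec.cov, rng=rng)
    else:
        etas = rng.standard_normal((n, m)) * np.asarray(spec.sds)
    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(spec.names):
        data[name] = pop_values[name] * np.exp(etas[:, j] * spec.mc_switch)
        data[f"eta_{name}"] = etas[:, j]
    return PopulationSample(data)


def empirical_covariance(etas: np.ndarray) -> np.ndarray:
    """Uncentered empirical covariance: ``Omega[j,k] = mean_i(eta_ij * eta_ik)``.

    The means of the etas are structurally zero, so the uncentered estimator
    matches the plausibility check applied in interactive use.  Symmetric by
    construction.
    """
    etas = np.atleast_2d(np.asarray(etas, dtype=float))
    return etas.T @ etas / etas.shape[0]


def sample_bodyweight(dist, n: int, mc_switch: int = 1, seed=None,
                      rng: np.random.Generator | None = None,
                      typical: float | None = None) -> np.ndarray:
    """Body weights from ``("normal", mean, sd)`` or ``("uniform", lo, hi)``.

    With ``mc_switch = 0`` every subject gets the typical value: the mean for
    the normal, the midpoint for the uniform unless an explicit ``typical``
    (e.g. the conventional 70 kg reference adult) is supplied.  Non-positive
    normal draws are resampled — weights must be physical.
    """
    if mc_switch not in (0, 1):
        raise ValueError("mc_switch must be 0 or 1")
    kind, a, b = dist[0], float(dist[1]), float(dist[2])
    if kind == "normal":
        center = typical if typical is not None else a
        if mc_switch == 0:
            return np.full(n, center)
        if rng is None:
            rng = np.random.default_rng(seed)
        w = rng.normal(a, b, size=n)
        while np.any(w <= 0):
            bad = w <= 0
            w[bad] = rng.normal(a, b, size=int(bad.sum()))
        return w
    if kind == "uniform":
        if a >= b:
            raise ValueError("uniform bounds must satisfy lo < hi")
        center = typical if typical is not None else (a + b) / 2.0
        if mc_switch == 0:
            return np.full(n, center)
        if rng is None:
            rng = np.random.default_rng(seed)
        return rng.uniform(a, b, size=n)
    raise ValueError(f"unknown body-weight distribution {kind!r}")
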