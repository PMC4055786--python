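"""Structural PK and PD model library.

Right-hand-side builders for the standard compartmental building blocks —
first-order oral absorption, peripheral distribution, transit-compartment
chains, saturable absorption, full-binding target-mediated drug disposition
(TMDD) — plus the algebraic PD components (circadian baseline modulation,
placebo time course, Emax, logistic, indirect response, flare probability)
and the closed-form solutions used as test oracles.

Builders return a :class:`Model`: a named state vector, a vectorized
``rhs(t, y, u)`` (``u`` is the per-compartment zero-order input rate supplied
by the engine), default initial amounts, and optional derived-output maps
(concentrations).  Parameters may be scalars or per-subject arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Callable

import numpy as np
from scipy.special import expit

__all__ = [
    "Model",
    "PKParams",
    "TMDDParams",
    "PDParams",
    "MODEL_BUILDERS",
    "build_model",
    "one_compartment_bolus",
    "one_compartment_oral",
    "two_compartment_oral",
    "three_compartment_oral",
    "two_compartment_clearance",
    "transit_chain",
    "saturable_absorption",
    "tmdd",
    "tmdd_dose_regimen",
    "one_compartment_oral_rhs",
    "multi_compartment_rhs",
    "transit_chain_rhs",
    "tmdd_rhs",
    "tmdd_concentrations",
    "circadian_factor",
    "placebo_factor",
    "emax_effect",
    "logistic_response",
    "indirect_effect_rhs",
    "flare_probability",
    "analytic_reference",
]


@dataclass
class Model:
    """A structural model: named states, vectorized RHS, init and outputs."""

    name: str
    state_names: tuple[str, ...]
    rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    init: dict[str, float | np.ndarray] = field(default_factory=dict)
    outputs: Callable | None = None
    params: dict = field(default_factory=dict)
    builder: Callable | None = None

    def with_params(self, **changes) -> "Model":
        """Rebuild the model with some parameters replaced."""
        if self.builder is None:
            raise ValueError(f"model {self.name!r} has no builder to rebuild from")
        unknown = set(changes) - set(self.params)
        if unknown:
            raise KeyError(
                f"parameter(s) {sorted(unknown)} not in model {self.name!r}; "
                f"available: {sorted(self.params)}"
            )
        return self.builder(**{**self.params, **changes})


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class PKParams:
    """Rate constants, clearances and volumes for the linear PK blocks."""

    ka: float = 0.1
    ke: float = 0.2
    k23: float = 0.3
    k32: float = 0.2
    CL: float = 1.0
    V1: float = 1.0
    V2: float = 33.0
    V3: float = 1.0
    PS: float = 0.1
    ktr: float = 0.25
    n_transit: int = 15
    kout: float = 0.25
    absmax: float = 20.0


@dataclass(frozen=True)
class TMDDParams:
    """Full-binding TMDD parameters (monoclonal-antibody defaults, time in days).

    The binding is reparameterized through the equilibrium dissociation
    constant: ``koff = Kd * kon``.  Drug amounts are carried in nmol;
    ``drug_conc_factor`` (0.15 mg/nmol, i.e. a 150 kDa antibody) and
    ``target_conc_factor`` (190) convert molar amounts to the reported
    concentration scales.  The unit annotations of the concentration outputs
    are inconsistent in the source material and should be treated as labels
    only.
    """

    kon: float = 1.0
    Kd: float = 1.5
    keD: float = 0.03
    keT: float = 0.5
    keTD: float = 0.1
    RateT: float = 50.0
    V: float = 7.0
    ka: float = 1.0
    drug_conc_factor: float = 0.15
    target_conc_factor: float = 190.0

    @property
    def koff(self) -> float:
        return self.Kd * self.kon

    def __post_init__(self) -> None:
        for name in ("kon", "Kd", "keD", "keT", "keTD", "RateT", "V", "ka"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.keT <= 0 and self.RateT > 0:
            raise ValueError("keT must be > 0 when RateT > 0 (initial T = RateT/keT)")


@dataclass(frozen=True)
class PDParams:
    """Parameters of the algebraic/turnover PD components."""

    amp: float = 0.1
    tshift: float = 10.0
    BL: float = 100.0
    maxdown: float = 0.1
    maxup: float = 0.1
    ratedown: float = 1.0
    rateup: float = 0.3
    E0: float = 25.0
    Emax: float = 50.0
    EC50: float = 40.0
    PD_in: float = 0.1
    PD_out: float = 0.1
    a: float = 0.0
    b: float = 1.0
    KIEF: float = 1.13
    HILL: float = 4.22

    def __post_init__(self) -> None:
        if self.amp < 0:
            raise ValueError("amp must be >= 0")
        if self.EC50 <= 0 or self.KIEF <= 0 or self.HILL <= 0:
            raise ValueError("EC50, KIEF and HILL must be > 0")


# ---------------------------------------------------------------------------
# Plain RHS operations (scalar/broadcast forms)


def one_compartment_oral_rhs(state, ka, ke, input_rate=0.0):
    """Depot + central: d(depot) = input - ka*depot; d(central) = ka*depot - ke*central."""
    depot, central = state
    absorbed = ka * depot
    return (input_rate - absorbed, absorbed - ke * central)


def multi_compartment_rhs(state, params: PKParams, input_rate=0.0):
    """Three compartments: depot -> central <-> peripheral, elimination from central."""
    comp1, comp2, comp3 = state
    absorbed = params.ka * comp1
    return (
        input_rate - absorbed,
        absorbed - params.k23 * comp2 + params.k32 * comp3 - params.ke * comp2,
        params.k23 * comp2 - params.k32 * comp3,
    )


def transit_chain_rhs(transit, Aplasma, ktr, kout, input_rate=0.0):
    """Transit-compartment absorption chain feeding a plasma compartment."""
    transit = np.asarray(transit, dtype=float)
    if transit.shape[0] < 1:
        raise ValueError("need n_transit >= 1")
    d = np.empty_like(transit)
    d[0] = input_rate - ktr * transit[0]
    if transit.shape[0] > 1:
        d[1:] = ktr * transit[:-1] - ktr * transit[1:]
    d_plasma = ktr * transit[-1] - kout * np.asarray(Aplasma, dtype=float)
    return d, d_plasma


def tmdd_rhs(S, D, T, TD, params: TMDDParams, input_rate=0.0):
    """Full-binding TMDD in molar amounts; binding flux is second order in concentration."""
    p = params
    bind = p.kon / p.V * D * T - p.koff * TD
    return (
        input_rate - p.ka * S,
        -bind - p.keD * D + p.ka * S,
        -bind - p.keT * T + p.RateT,
        +bind - p.keTD * TD,
    )


def tmdd_concentrations(D, T, TD, params: TMDDParams) -> dict:
    """Reported concentration scales: free/total drug and free/total target."""
    p = params
    return {
        "CFD": p.drug_conc_factor * np.asarray(D) / p.V,
        "CTD": p.drug_conc_factor * (np.asarray(D) + np.asarray(TD)) / p.V,
        "CFT": p.target_conc_factor * np.asarray(T) / p.V,
        "CTT": p.target_conc_factor * (np.asarray(T) + np.asarray(TD)) / p.V,
    }


# ---------------------------------------------------------------------------
# Algebraic PD components


def circadian_factor(t, amp, tshift):
    """Multiplicative 24 h cosine modulation: 1 + amp*cos(2*pi*(t - tshift)/24)."""
    return 1.0 + amp * np.cos(2.0 * np.pi * (np.asarray(t, dtype=float) - tshift) / 24.0)


def placebo_factor(t, maxdown=0.1, maxup=0.1, ratedown=1.0, rateup=0.3):
    """Multiplicative placebo time course that can appear and partially persist.

    ``1 + maxup*(1 - exp(-rateup*t)) - maxdown*(1 - exp(-ratedown*t))``;
    the response is the baseline times this factor.
    """
    t = np.asarray(t, dtype=float)
    up = maxup * (1.0 - np.exp(-rateup * t))
    down = maxdown * (1.0 - np.exp(-ratedown * t))
    return 1.0 + up - down


def emax_effect(C, E0, Emax, EC50):
    """Saturating concentration-effect: E0 + Emax*C/(C + EC50)."""
    C = np.asarray(C, dtype=float)
    return E0 + Emax * C / (C + EC50)


def logistic_response(a, b, x):
    """Logistic probability exp(a + b*x)/(1 + exp(a + b*x)), numerically stable."""
    return expit(a + b * np.asarray(x, dtype=float))


def indirect_effect_rhs(PD, C, PD_in, PD_out):
    """Turnover effect compartment: d(PD) = PD_in*C - PD_out*PD."""
    return PD_in * np.asarray(C, dtype=float) - PD_out * np.asarray(PD, dtype=float)


def flare_probability(C, KIEF, HILL):
    """Probability of a disease flare, declining in drug concentration.

    ``1 - C^HILL / (KIEF^HILL + C^HILL)``; equals 1 without drug, 0.5 at
    ``C = KIEF``, and falls towards 0 at high exposure.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be >= 0")
    if np.any(np.asarray(KIEF) <= 0) or np.any(np.asarray(HILL) <= 0):
        raise ValueError("KIEF and HILL must be > 0")
    # (C/KIEF)^H formulation keeps precision for large C; an overflowing
    # ratio saturates cleanly at probability 0
    with np.errstate(over="ignore"):
        ratio = (C / KIEF) ** HILL
        return 1.0 / (1.0 + ratio)


# ---------------------------------------------------------------------------
# Closed-form oracles


def analytic_reference(model_id: str, params: dict, t):
    """Closed-form drug amount for simple reference models.

    ``one_cpt_bolus``: dose*exp(-ke*t).
    ``one_cpt_oral_bateman``: dose*ka/(ka-ke)*(exp(-ke*t) - exp(-ka*t)),
    with the analytic limit dose*ka*t*exp(-ka*t) as ka -> ke.
    """
    t = np.asarray(t, dtype=float)
    if model_id == "one_cpt_bolus":
        return params["dose"] * np.exp(-params["ke"] * t)
    if model_id == "one_cpt_oral_bateman":
        dose, ka, ke = params["dose"], params["ka"], params["ke"]
        if abs(ka - ke) < 1e-10 * abs(ka):
            return dose * ka * t * np.exp(-ka * t)
        return dose * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    raise ValueError(f"unknown analytic model {model_id!r}")


# ---------------------------------------------------------------------------
# Model builders


def one_compartment_bolus(ke=0.2, V=1.0) -> Model:
    def rhs(t, y, u):
        return np.stack([u[0] - ke * y[0]])

    def outputs(times, states):
        return {"conc": states["central"] / V}

    return Model("one_cpt_bolus", ("central",), rhs, outputs=outputs,
                 params={"ke": ke, "V": V}, builder=one_compartment_bolus)


def one_compartment_oral(ka=0.1, ke=0.2, V=1.0) -> Model:
    def rhs(t, y, u):
        absorbed = ka * y[0]
        return np.stack([u[0] - absorbed, absorbed - ke * y[1]])

    def outputs(times, states):
        return {"conc": states["central"] / V}

    return Model("one_cpt_oral", ("depot", "central"), rhs, outputs=outputs,
                 params={"ka": ka, "ke": ke, "V": V}, builder=one_compartment_oral)


def two_compartment_oral(ka=0.4, ke=0.1, k23=0.3, k32=0.2, V=1.0) -> Model:
    """Depot, central and peripheral compartments with rate-constant transfer."""

    def rhs(t, y, u):
        absorbed = ka * y[0]
        return np.stack([
            u[0] - absorbed,
            absorbed - k23 * y[1] + k32 * y[2] - ke * y[1],
            k23 * y[1] - k32 * y[2],
        ])

    def outputs(times, states):
        return {"conc": states["central"] / V}

    return Model("two_cpt_oral", ("depot", "central", "peripheral"), rhs,
                 outputs=outputs,
                 params={"ka": ka, "ke": ke, "k23": k23, "k32": k32, "V": V},
                 builder=two_compartment_oral)


# counting the depot, this is a three-compartment system: alias for that naming
three_compartment_oral = two_compartment_oral


def two_compartment_clearance(CL=0.181, V2=5.07, PS=0.103, V3=1.74, ka=0.438) -> Model:
    """Subcutaneous depot + central/peripheral in clearance parameterization.

    d(D) = ka*S - D*CL/V2 + PS*(T/V3 - D/V2) with peripheral amount T.
    """

    def rhs(t, y, u):
        S, D, T = y[0], y[1], y[2]
        exch = PS * (T / V3 - D / V2)
        return np.stack([
            u[0] - ka * S,
            ka * S - D * CL / V2 + exch,
            -exch,
        ])

    def outputs(times, states):
        return {"conc": states["central"] / V2}

    return Model("two_cpt_clearance", ("depot", "central", "peripheral"), rhs,
                 outputs=outputs,
                 params={"CL": CL, "V2": V2, "PS": PS, "V3": V3, "ka": ka},
                 builder=two_compartment_clearance)


def transit_chain(ktr=0.25, kout=0.25, n_transit=15) -> Model:
    if n_transit < 1:
        raise ValueError("n_transit must be >= 1")
    n_transit = int(n_transit)

    def rhs(t, y, u):
        d = np.empty_like(y)
        d[0] = u[0] - ktr * y[0]
        if n_transit > 1:
            d[1:n_transit] = ktr * (y[: n_transit - 1] - y[1:n_transit])
        d[n_transit] = ktr * y[n_transit - 1] - kout * y[n_transit]
        return d

    names = tuple(f"transit{i + 1}" for i in range(n_transit)) + ("plasma",)
    return Model("transit_chain", names, rhs,
                 params={"ktr": ktr, "kout": kout, "n_transit": n_transit},
                 builder=transit_chain)


def saturable_absorption(ka=1.0, ke=0.05, absmax=20.0) -> Model:
    """First-order absorption capped at absmax mass/time."""
    from .engine import saturable_absorption_rate

    def rhs(t, y, u):
        absorbed = saturable_absorption_rate(y[0], ka, absmax)
        return np.stack([u[0] - absorbed, absorbed - ke * y[1]])

    return Model("saturable_absorption", ("depot", "central"), rhs,
                 params={"ka": ka, "ke": ke, "absmax": absmax},
                 builder=saturable_absorption)


def tmdd(params: TMDDParams | None = None, **overrides) -> Model:
    """Full-binding TMDD model in molar amounts, initialized at target turnover
    steady state (T0 = RateT/keT)."""
    if params is None:
        params = TMDDParams(**overrides)
    elif overrides:
        raise TypeError("pass either a TMDDParams or keyword overrides, not both")
    p = params

    def rhs(t, y, u):
        dS, dD, dT, dTD = tmdd_rhs(y[0], y[1], y[2], y[3], p, input_rate=u[0])
        return np.stack([dS, dD, dT, dTD])

    def outputs(times, states):
        return tmdd_concentrations(states["D"], states["T"], states["TD"], p)

    T0 = p.RateT / p.keT if p.RateT > 0 else 0.0

    def builder(**kw):
        return tmdd(TMDDParams(**kw))

    return Model("tmdd", ("S", "D", "T", "TD"), rhs,
                 init={"T": T0}, outputs=outputs,
                 params={f.name: getattr(p, f.name) for f in dc_fields(TMDDParams)},
                 builder=builder)


def tmdd_dose_regimen(dose_mg: float, params: TMDDParams, first_time=0.0,
                      interval=28.0, n_doses=0):
    """Subcutaneous dosing of ``dose_mg`` converted to nmol via the drug
    mass-per-mole factor, targeted at the injection-site compartment."""
    from .engine import DoseRegimen

    return DoseRegimen(amount=dose_mg / params.drug_conc_factor,
                       first_time=first_time, interval=interval,
                       n_doses=n_doses, target="S")


MODEL_BUILDERS: dict[str, Callable[..., Model]] = {
    "one_cpt_bolus": one_compartment_bolus,
    "one_cpt_oral": one_compartment_oral,
    "two_cpt_oral": two_compartment_oral,
    "two_cpt_clearance": two_compartment_clearance,
    "transit_chain": transit_chain,
    "saturable_absorption": saturable_absorption,
    "tmdd": tmdd,
}


def build_model(model_id: str, **params) -> Model:
    """Instantiate a structural model from the registry by identifier."""
    try:
        builder = MODEL_BUILDERS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available: {sorted(MODEL_BUILDERS)}"
        ) from None
    return builder(**params)
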