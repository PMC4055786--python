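"""Clinical-trial simulators.

Two fully parameterized trial designs are provided:

* **Blood-pressure success trial** — oral one-compartment PK with lognormal
  between-subject variability feeding a direct Emax effect on blood pressure;
  a study succeeds for a patient when the blood-pressure change at the
  evaluation time (72 h, read at trough) is below a threshold (-20 mmHg).
  The headline statistic is the percentage of successful patients; replicate
  studies quantify between-trial variability of that percentage and the
  dose-response of success supports dose selection.

* **Flare / randomized-withdrawal trial** — canakinumab-like subcutaneous
  two-compartment PK with allometric weight scaling and correlated lognormal
  random effects; all patients are treated from day 0, at day 56 one arm is
  randomized to placebo (withdrawal) while the other continues q56d dosing.
  At weekly visits after withdrawal a flare occurs as a Bernoulli event whose
  probability declines with drug concentration through a Hill function; the
  first flare transfers the patient out of the study (absorbing), and the
  per-arm flare-free fraction over visits forms Kaplan-Meier-like step curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import DoseRegimen, SolverConfig, Trajectory, integrate
from .models import (
    emax_effect,
    flare_probability,
    one_compartment_oral,
    two_compartment_clearance,
)
from .population import cholesky_upper, sample_bodyweight

__all__ = [
    "BPTrialDesign",
    "BPModelParams",
    "FlareTrialDesign",
    "FlareModelParams",
    "TrialResult",
    "canakinumab_dose",
    "simulate_bp_trial",
    "success_percent_at",
    "bp_dose_response",
    "simulate_flare_trial",
    "replicate_trials",
]


@dataclass(frozen=True)
class BPTrialDesign:
    """Design of the blood-pressure success trial (times in hours)."""

    dose: float = 150.0
    n_doses: int = 4
    dose_interval: float = 24.0
    n_subjects: int = 100
    eval_time: float = 72.0
    pd_threshold: float = -20.0
    residual_sd: float = 0.01
    start_time: float = -1.0
    stop_time: float = 144.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (self.start_time <= self.eval_time <= self.stop_time):
            raise ValueError("eval_time must lie within the simulation window")


@dataclass(frozen=True)
class BPModelParams:
    """PK/PD population parameters of the blood-pressure model.

    Lognormal random-effect sds apply to ka, ke, V1 and the baseline.
    """

    ka: float = 0.1
    ke: float = 0.1
    V1: float = 1.0
    E0: float = 125.0
    Emax: float = -40.0
    EC50: float = 20.0
    sd_ka: float = 1.0
    sd_ke: float = 0.01
    sd_V1: float = 0.2
    sd_BL: float = 0.1


@dataclass(frozen=True)
class FlareTrialDesign:
    """Design of the randomized-withdrawal flare trial (times in days)."""

    n_per_arm: int = 18
    tau: float = 56.0
    start_p2: float = 56.0
    start_time: float = -28.0
    stop_time: float = 224.0
    visit_freq: float = 7.0
    n_doses_p2: tuple[int, int] = (3, 0)
    weight_lo: float = 10.0
    weight_hi: float = 80.0
    mc_switch: int = 1
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.start_p2 < 0:
            raise ValueError("start_p2 must be >= first-dose time (0)")


@dataclass(frozen=True)
class FlareModelParams:
    """Canakinumab population PK and flare-probability parameters.

    Clearances/volumes are for a 70 kg reference patient and scale with
    body weight: linearly for CL, V2 and V3, with exponent 0.667 for PS.
    (CL, V2) and (PS, V3) carry correlated lognormal random effects with the
    covariance matrices below; ka, F and KIEF carry independent lognormal
    effects; the Hill coefficient is fixed.
    """

    CL: float = 0.181      # L/d at 70 kg
    V2: float = 5.07       # L
    PS: float = 0.103      # L/d
    V3: float = 1.74       # L
    ka: float = 0.438      # 1/d
    F: float = 0.663
    KIEF: float = 1.13     # ug/mL for 50:50 flare probability
    HILL: float = 4.22
    sd_ka: float = float(np.sqrt(0.185))
    sd_F: float = float(np.sqrt(0.0881))
    sd_KIEF: float = float(np.sqrt(0.0158))
    cov_cl_v2: tuple = ((0.0442, 0.0556), (0.0556, 0.0869))
    cov_ps_v3: tuple = ((0.366, 0.0153), (0.0153, 0.000651))
    allo_cl: float = 1.0
    allo_v2: float = 1.0
    allo_ps: float = 0.667
    allo_v3: float = 1.0


@dataclass
class TrialResult:
    """Per-subject outcomes plus trial-level statistics.

    Blood-pressure trials populate ``success``/``success_percent``; flare
    trials populate the visit-level fields.  ``subjects`` always carries the
    frozen individual parameters.
    """

    subjects: pd.DataFrame
    replicate: int = 0
    trajectory: Trajectory | None = None
    # blood-pressure trial
    success: np.ndarray | None = None
    success_percent: float | None = None
    eval_time: float | None = None
    # flare trial
    visit_times: np.ndarray | None = None
    flare_free: dict[int, np.ndarray] | None = None
    part3: np.ndarray | None = None
    flare_events: pd.DataFrame | None = None


def canakinumab_dose(weight):
    """Weight-banded posology: 2 mg/kg below 40 kg, otherwise a flat 150 mg."""
    weight = np.asarray(weight, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("weight must be > 0")
    return np.where(weight < 40.0, 2.0 * weight, 150.0)


# ---------------------------------------------------------------------------
# Blood-pressure trial


def simulate_bp_trial(design: BPTrialDesign | None = None,
                      params: BPModelParams | None = None,
                      seed=None, rng: np.random.Generator | None = None,
                      replicate: int = 0) -> TrialResult:
    """Simulate one blood-pressure study of ``n_subjects`` patients.

    Each patient gets individual lognormal ka, ke, V1 and baseline; the PK is
    an oral one-compartment model dosed daily.  Concentration at the
    evaluation time carries a multiplicative residual ``exp(N(0, sd))``; the
    drug effect is ``Emax*C/(C + EC50)`` and a patient is a success when that
    change is below the threshold.  Evaluation at 72 h is a trough: the 72 h
    dose enters the depot and does not contribute to the concentration read.
    """
    design = design or BPTrialDesign()
    params = params or BPModelParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = design.n_subjects

    eta_ka = rng.normal(0.0, params.sd_ka, n)
    eta_ke = rng.normal(0.0, params.sd_ke, n)
    eta_V1 = rng.normal(0.0, params.sd_V1, n)
    eta_BL = rng.normal(0.0, params.sd_BL, n)
    ka_i = params.ka * np.exp(eta_ka)
    ke_i = params.ke * np.exp(eta_ke)
    V1_i = params.V1 * np.exp(eta_V1)
    BL_i = params.E0 * np.exp(eta_BL)

    model = one_compartment_oral(ka=ka_i, ke=ke_i, V=V1_i)
    regimen = DoseRegimen(amount=design.dose, first_time=0.0,
                          interval=design.dose_interval, n_doses=design.n_doses,
                          target="depot")
    config = SolverConfig(start_time=design.start_time, stop_time=design.stop_time,
                          method="rk4", dt=design.dt)
    traj = integrate(model, regimen, config,
                     init_state={"depot": np.zeros(n), "central": np.zeros(n)})

    idx = _match_time(traj.times, design.eval_time, design.dt)
    conc_eval = traj["central"][idx] / V1_i * np.exp(
        rng.normal(0.0, design.residual_sd, n))
    pd_change = emax_effect(conc_eval, 0.0, params.Emax, params.EC50)
    success = pd_change < design.pd_threshold
    subjects = pd.DataFrame({
        "ka": ka_i, "ke": ke_i, "V1": V1_i, "baseline": BL_i,
        "eta_ka": eta_ka, "eta_ke": eta_ke, "eta_V1": eta_V1, "eta_BL": eta_BL,
        "conc_eval": conc_eval, "pd_change": pd_change,
        "bp": BL_i + pd_change, "success": success,
    })
    return TrialResult(subjects=subjects, replicate=replicate, trajectory=traj,
                       success=success,
                       success_percent=100.0 * float(np.mean(success)),
                       eval_time=design.eval_time)


def success_percent_at(times: np.ndarray, pd_change: np.ndarray,
                       eval_time: float, dt: float, threshold: float) -> float:
    """Percentage of subjects below ``threshold`` at the grid time matching
    ``eval_time`` (first time within ``dt`` of it)."""
    idx = _match_time(np.asarray(times, dtype=float), eval_time, dt)
    values = np.asarray(pd_change)[idx]
    return 100.0 * float(np.mean(values < threshold))


def _match_time(times: np.ndarray, eval_time: float, dt: float) -> int:
    hits = np.nonzero(np.abs(times - eval_time) < dt)[0]
    if hits.size == 0:
        raise ValueError(
            f"no output time within {dt} of eval_time={eval_time}")
    return int(hits[0])


def bp_dose_response(dose_grid: Sequence[float], n_replicates: int,
                     design: BPTrialDesign | None = None,
                     params: BPModelParams | None = None,
                     seed=None) -> pd.DataFrame:
    """Replicate studies over a dose grid.

    Returns a tidy table with one row per (replicate, dose) and the resulting
    success percentage; overlaying the replicate curves visualizes
    between-trial variability of the dose-response.
    """
    dose_grid = list(dose_grid)
    if not dose_grid:
        raise ValueError("dose grid must be non-empty")
    design = design or BPTrialDesign()
    params = params or BPModelParams()
    streams = np.random.SeedSequence(seed).spawn(n_replicates * len(dose_grid))
    rows = []
    k = 0
    for rep in range(n_replicates):
        for dose in dose_grid:
            d = BPTrialDesign(**{**design.__dict__, "dose": float(dose)})
            res = simulate_bp_trial(d, params,
                                    rng=np.random.default_rng(streams[k]),
                                    replicate=rep)
            rows.append({"replicate": rep, "dose": float(dose),
                         "success_percent": res.success_percent})
            k += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flare / randomized-withdrawal trial


def simulate_flare_trial(design: FlareTrialDesign | None = None,
                         params: FlareModelParams | None = None,
                         seed=None, rng: np.random.Generator | None = None,
                         replicate: int = 0) -> TrialResult:
    """Simulate one randomized-withdrawal flare trial.

    Both arms receive the weight-banded dose at day 0.  At ``start_p2``
    (day 56) arm 0 continues with ``n_doses_p2[0]`` further doses every
    ``tau`` days while arm 1 is withdrawn to placebo.  At each weekly visit
    strictly after ``start_p2`` a flare is drawn as Bernoulli with
    probability given by the Hill decline in total drug concentration; the
    first flare transfers the patient to the open-label part (absorbing).
    """
    design = design or FlareTrialDesign()
    params = params or FlareModelParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    n_arm = design.n_per_arm
    n = 2 * n_arm
    arm = np.repeat([0, 1], n_arm)
    mc = design.mc_switch

    wt = sample_bodyweight(("uniform", design.weight_lo, design.weight_hi),
                           n, mc_switch=mc, rng=rng, typical=70.0)
    dose = canakinumab_dose(wt)

    ch1 = cholesky_upper(np.asarray(params.cov_cl_v2))
    ch2 = cholesky_upper(np.asarray(params.cov_ps_v3))
    eta1 = rng.standard_normal((n, 2)) @ ch1
    eta2 = rng.standard_normal((n, 2)) @ ch2
    rel = wt / 70.0
    CL_i = params.CL * rel ** params.allo_cl * np.exp(eta1[:, 0] * mc)
    V2_i = params.V2 * rel ** params.allo_v2 * np.exp(eta1[:, 1] * mc)
    PS_i = params.PS * rel ** params.allo_ps * np.exp(eta2[:, 0] * mc)
    V3_i = params.V3 * rel ** params.allo_v3 * np.exp(eta2[:, 1] * mc)
    ka_i = params.ka * np.exp(rng.normal(0.0, params.sd_ka, n) * mc)
    F_i = params.F * np.exp(rng.normal(0.0, params.sd_F, n) * mc)
    KIEF_i = params.KIEF * np.exp(rng.normal(0.0, params.sd_KIEF, n) * mc)

    model = two_compartment_clearance(CL=CL_i, V2=V2_i, PS=PS_i, V3=V3_i, ka=ka_i)
    # the sampled bioavailability is lognormal and may exceed 1, so it is
    # folded into the administered amount rather than the regimen F field
    first = DoseRegimen(amount=dose * F_i, first_time=0.0,
                        interval=design.tau, n_doses=1, target="depot")
    # Part-2/3 doses: an exact per-arm dose count (the withdrawn arm gets none)
    regimens = [first]
    for a in (0, 1):
        nd = design.n_doses_p2[a]
        if nd > 0:
            regimens.append(DoseRegimen(
                amount=np.where(arm == a, dose * F_i, 0.0),
                first_time=design.start_p2, interval=design.tau,
                n_doses=nd, target="depot"))
    config = SolverConfig(start_time=design.start_time, stop_time=design.stop_time,
                          method="rk4", dt=design.dt)
    zeros = np.zeros(n)
    traj = integrate(model, regimens, config,
                     init_state={"depot": zeros, "central": zeros,
                                 "peripheral": zeros})
    conc = traj["central"] / V2_i  # ug/mL total drug

    n_visits = int(np.floor((design.stop_time - design.start_time)
                            / design.visit_freq + 1e-9)) + 1
    visit_times = design.start_time + np.arange(n_visits) * design.visit_freq
    part3 = np.zeros((n_visits, n), dtype=int)
    events = []
    state = np.zeros(n, dtype=int)
    for v, t in enumerate(visit_times):
        if t > design.start_p2:
            i = _match_time(traj.times, t, design.dt)
            p = flare_probability(conc[i], KIEF_i, params.HILL)
            flare = rng.binomial(1, p)
            newly = (flare == 1) & (state == 0)
            state = np.minimum(1, state + flare)
            for j in np.nonzero(newly)[0]:
                events.append({"subject": int(j), "arm": int(arm[j]),
                               "visit_time": float(t),
                               "conc": float(conc[i][j]),
                               "p_flare": float(p[j])})
        part3[v] = state

    flare_free = {
        a: 1.0 - part3[:, arm == a].sum(axis=1) / n_arm for a in (0, 1)
    }
    subjects = pd.DataFrame({
        "arm": arm, "weight": wt, "dose": dose,
        "CL": CL_i, "V2": V2_i, "PS": PS_i, "V3": V3_i,
        "ka": ka_i, "F": F_i, "KIEF": KIEF_i,
        "flared": state.astype(bool),
    })
    return TrialResult(subjects=subjects, replicate=replicate, trajectory=traj,
                       visit_times=visit_times, flare_free=flare_free,
                       part3=part3,
                       flare_events=pd.DataFrame(
                           events, columns=["subject", "arm", "visit_time",
                                            "conc", "p_flare"]))


def replicate_trials(n_replicates: int,
                     design: FlareTrialDesign | None = None,
                     params: FlareModelParams | None = None,
                     seed=None) -> list[TrialResult]:
    """Independent replicate flare trials with per-replicate random streams."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    # replicate 0 uses the master seed directly (so a single replicate equals a
    # plain simulate_flare_trial call); further replicates use spawned streams
    children = (np.random.SeedSequence(seed).spawn(n_replicates - 1)
                if n_replicates > 1 else [])
    rngs = [np.random.default_rng(seed)] + [np.random.default_rng(c)
                                            for c in children]
    return [
        simulate_flare_trial(design, params, rng=rngs[k], replicate=k)
        for k in range(n_replicates)
    ]
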