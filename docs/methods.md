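# Methods

This note records the modelling conventions, numerical choices and known
limitations of `pmxsim`. It is the place where design decisions that were
genuinely open are written down.

## Dosing events

A bolus is a discrete state increment of `amount × bioavailability` applied
at the first output-grid point at or after the scheduled time. Doses that
fall between grid points are snapped *forward* to the next grid point and a
warning is logged; mass is always delivered exactly once and in full. The
state recorded at a dose time is the *post-dose* state, which makes total
drug amount equal the cumulative administered amount at every output time in
elimination-free systems (the mass-conservation invariant the test suite
asserts to 1e-9 relative).

This replaces the triangular-pulse approximation used by interactive
simulators, which spreads a dose over two integration steps and can deliver
half a dose at window edges depending on version and step size. For the same
reason the Part-2 dosing window of the flare trial is expressed as an exact
dose count rather than a time-window comparison involving the step size.

Zero-order infusions enter the right-hand side as a rate that is switched on
inside periodic windows (`t mod interval < duration`). For fixed-step
methods the input rate is sampled at the step start and held constant over
the step, so windows aligned with the grid deliver exactly
`rate × duration` per interval; off-grid window edges are resolved to one
step.

Simulations conventionally start one step (or one time unit) before the
first dose; a dose exactly at the start time is supported but starting
earlier avoids edge effects in general.

## Solvers

`euler`, `rk2` (midpoint) and `rk4` (classical) are fixed-step methods on a
grid anchored at `start_time`; a final partial step lands exactly on
`stop_time` when the window is not a multiple of `dt`. `adaptive_stiff`
wraps a variable-step implicit solver (LSODA) honouring `tolerance`
(relative; absolute tolerance is 1e-3 of it), `dt_min` and `dt_max`, and is
restarted at every bolus time so the discontinuity never falls inside an
accepted step. `dt_out = 0` returns every accepted step; `dt_out > 0`
returns an even grid (by subsetting when aligned with `dt`, otherwise by
interpolation; dense-output interpolation for the adaptive method).

RK4 at `dt = 0.02` reproduces the one-compartment bolus and Bateman closed
forms to ~1e-11 relative over 100 h — far inside the 1e-6 the tests demand —
so fixed-step RK4 is the default for all non-stiff work. The TMDD system is
integrated with `adaptive_stiff` (tolerance 1e-3, `dt_min` 1e-3 d, `dt_max`
0.1 d over days −28 to 84), the settings under which its figures-of-merit
(steady-state constancy, dose-ordering of total target) are asserted.

The Bateman oracle switches to the analytic `ka = ke` limit
(`dose·ka·t·e^(−ka·t)`) when `|ka − ke| < 1e-10·ka` so the test oracle
cannot lose precision near the degenerate case.

## Random effects and reproducibility

Individual parameters are lognormal, `p_i = p_pop·exp(η_i·MC)`, with the
Monte-Carlo switch `MC ∈ {0, 1}` collapsing the population to the typical
subject. Correlated η's come from `r @ CH` where `r` is standard normal and
`CH` the upper Cholesky factor (`CHᵀCH = COV`), computed at run time with
LAPACK via numpy — never hand-entered; the historically hand-copied factor
values survive as regression tests. The empirical covariance check uses the
uncentered estimator `Ω = ηᵀη/n` (η means are structurally zero); a centered
variant can be had by centering beforehand.

All randomness flows from one seed. The standard-normal block for a
population is drawn row-major (one row per subject) from a single PCG64
stream, so enlarging the population appends subjects without changing the
draws of earlier ones. Replicate trials use spawned child streams
(`SeedSequence.spawn`); replicate 0 uses the master seed directly so a
single replicate equals a plain simulation call with that seed.

Residual (within-subject) error on concentrations is multiplicative
lognormal, `C·exp(N(0, sd))`. The sd is interpreted as a standard deviation
(not a variance); with the conventional `sd = 0.01` the residual is
negligible next to the between-subject spread, but the interpretation would
matter at larger values. Simulated trajectories are noise-free; the residual
is drawn once per subject where an observation is actually "taken" (at the
trial evaluation time, or at the sampling times of the fixture generator),
not at every integration step.

Body weights drawn from a normal distribution are resampled if non-positive
(physically meaningless; negligible probability at the default
mean 70 / sd 10). With variability off, normal weights collapse to the mean
and uniform weights to an explicit typical value — the flare trial uses the
conventional 70 kg reference adult, not the midpoint of its 10–80 kg range.

## The blood-pressure trial

Oral one-compartment PK (`ka = ke = 0.1 /h`, `V1 = 1 L`), daily dosing for
4 doses, lognormal η's with sds 1.0 (ka), 0.01 (ke), 0.2 (V1) and 0.1 on the
baseline (E0 = 125 mmHg); drug effect `Emax·C/(C+EC50)` with
`Emax = −40 mmHg`, `EC50 = 20 ng/mL`. A patient is a success when the change
is below −20 mmHg at 72 h. The 72 h read is a trough by construction: the
72 h dose enters the depot and cannot contribute to the central
concentration at that instant. The headline behaviour — at 150 mg daily all
(occasionally 9 of) 10 replicate 100-patient studies reach ≥80% success —
is recomputed by `scripts/acceptance.py`.

One incidental quirk of the source listing: it defines individual `ke`
values but eliminates with the population `ke`. `pmxsim` uses the individual
values; at sd 0.01 the difference is far below Monte-Carlo noise.

## The flare trial

Two arms of 18 patients, uniform(10, 80) kg weights, weight-banded dosing
(2 mg/kg below 40 kg, else 150 mg). Subcutaneous two-compartment PK in
clearance form with reference parameters CL 0.181 L/d, V2 5.07 L,
PS 0.103 L/d, V3 1.74 L at 70 kg; CL, V2, V3 scale linearly with weight and
PS with exponent 0.667. (CL, V2) and (PS, V3) carry correlated lognormal
effects with covariances [[0.0442, 0.0556], [0.0556, 0.0869]] and
[[0.366, 0.0153], [0.0153, 0.000651]]; ka (0.438/d), F (0.663) and KIEF
(1.13 µg/mL) carry independent lognormal effects with variances 0.185,
0.0881 and 0.0158; the Hill coefficient is 4.22. Because the sampled
bioavailability is lognormal it can exceed 1; it is folded into the
administered amount rather than the regimen's bounded F field.

All patients are dosed at day 0; at day 56 arm 0 receives 3 further doses
every 56 days while arm 1 is withdrawn. Visits run every 7 days from day
−28; flares are counted only at visits strictly after day 56, as Bernoulli
draws with `P = 1 − C^H/(KIEF^H + C^H)` evaluated at the visit-time total
drug concentration `D/V2`. The first flare is absorbing (a patient transfers
once, never back), and the per-arm flare-free fraction
`1 − transfers/N` over visits forms the step curves replicate runs overlay.
Integration is RK4 at `dt = 1 d` — adequate because the kinetics have
multi-day half-lives — and one replicate simulates all 36 patients as one
vectorized state array.

No numeric flare-curve values are published for this design, so the test
suite asserts the structural properties instead: curves start at 1 and never
increase, transfer is absorbing, and averaged over 200 replicates the
withdrawn arm's flare-free fraction lies at or below the treated arm's from
day 84 onward within a 99% normal-approximation binomial band of the
difference.

## Evaluation and fitting

`statistic_at_time` reads the first output time `t` with
`|t − eval_time| < dt` — the direct equivalent of the interactive
sentinel-and-max trick, without infinities leaking into exports. When the
evaluation time sits between grid points both neighbours may satisfy the
window; the first (earlier) match wins, a deliberate tie-break. A missing
match returns `None`.

Parameter sweeps rebuild the model (or regimen) per grid value and run a
full simulation each; `steps = n` produces the even grid
`start + k·(stop−start)/(n−1)`. Summary intervals are `m ± z·sd` with the
population-denominator sd and `z` defaulting to the inverse-normal 97.5th
percentile (1.96 to two decimals), computed, not hard-coded.

Least-squares fitting minimizes the unweighted RSS between observations and
the trajectory output linearly interpolated at the observation times, via
Nelder–Mead restarts from each provided guess (two guesses per parameter are
customary; the best local optimum is kept). All observations are treated as
independent — subject structure is deliberately ignored — so estimates are
starting values for mixed-effects tools, not population estimates. The
ka/ke flip-flop ambiguity of the Bateman model is documented, not resolved.
Non-convergence is flagged on the result, never raised.

## What the synthetic data do and do not show

The fixture generator produces observations as
`prediction·exp(N(0, noise_sd))` from the very model class being fitted.
Passing recovery tests therefore demonstrates correctness of the
simulation–estimation loop, not robustness to model misspecification,
dropout, censoring, or assay limits — none of which are modelled. Trial
simulations likewise inherit every structural assumption of their models
(no dropout, perfect adherence, visit-exact observation); their value is in
propagating parameter uncertainty and sampling variability, not in
validating the structural model itself.

## Problem sizes

Default sizes are the study conditions themselves: 100 patients and 10
replicates for the blood-pressure trial, 2×18 patients for the flare trial
with 200 replicates in the replicate-property checks, 1e5 draws for
Monte-Carlo covariance recovery. The full test suite runs in about a minute
on one CPU.
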