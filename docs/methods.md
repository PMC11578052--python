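# Methods

## Model structure

The core is a deterministic Markov cohort model over eleven health states:
`disease_free`; an acute and a chronic state for each of four nonfatal CVD
event types (acute myocardial infarction, other ischemic heart disease,
ischemic stroke, hemorrhagic stroke); and two absorbing states (`fatal_cvd`,
`non_cvd_death`). The state order is fixed (`bpcea.states.STATE_SPACE`) so
matrices and occupancy vectors are position-stable. Acute myocardial
infarction is kept separate from other ischemic heart disease because its
hospitalization cost differs substantially.

Cycles are annual and the horizon is lifetime (default cutoff age 100; the
run also stops once unabsorbed mass falls below 1e-9). The cohort starts
with probability 1 in `disease_free` at the chosen start age.

**Acute states are one-cycle tunnels.** An acute state may be occupied for
exactly one cycle; its row routes all non-death mass to the chronic twin.
The acute stage corresponds to the hospitalization episode; one annual cycle
is the coarsest representation consistent with annual cycling, and the acute
state carries the per-event hospitalization plus acute indirect cost.

**Comorbidity is memoryless.** A person in a chronic state who has another
event (same or different type) moves to that event's acute state; only the
current state is tracked (Markov property). Transitions between nonfatal
event types are reciprocal.

## Transition probabilities

Baseline inputs are 10-year cumulative probabilities indexed by age band
(35–44, 45–54, 55–64, 65–75):

* first-event probabilities from `disease_free`, per event type;
* fatal-CVD and non-CVD-death probabilities from `disease_free`;
* between-event probabilities out of each chronic state (recurrence,
  cross-event shifts, and death), estimated on wide age groups (35–75,
  45–75, 55–75, 65–75) because recurrent events are sparse; the group is
  selected once per run by the cohort's starting age.

Ten-year probabilities convert to annual ones by
`r = 1 − exp(ln(1−p)/10)` (constant-rate assumption; the exact inverse
`p = 1 − (1−r)^10` holds to machine precision and is property-tested).
Parameter files tag the horizon explicitly (`horizon_years: 10`) so the
conversion is auditable.

The matrix is rebuilt whenever the cohort crosses an age-band boundary (age
= start age + cycle). Ages beyond the oldest band reuse that band's
probabilities; lifetime horizons extend past 75 and constant extrapolation
is the least-assumption choice, at the cost of understating very-old-age
mortality (a known limitation).

## Effect translation

Intervention evidence enters as hazard ratios per reference SBP reduction
(per 10 mm Hg by outcome and age band, or a single pooled HR such as 0.89
per 5 mm Hg from drug-trial meta-analysis). Under log-linearity of CVD risk
in SBP, an intervention reducing SBP by δ mm Hg acts with
`HR(δ) = HR(ref)^(δ/ref)`; this makes HR scaling additive in δ
(property-tested). Defaults: salt substitution δ = 2, drug treatment
δ = 5.6, combination = both components with multiplied effects.

Multipliers are applied in the **rate domain**: `p' = 1 − (1−p)^HR`. This
keeps probabilities in [0, 1) for any positive multiplier and makes
composition exact (applying HR₁ then HR₂ equals applying HR₁·HR₂). Applying
HRs directly to probabilities would violate both properties.

Effects multiply CVD-event and fatal-CVD hazards only, never non-CVD death.
By default they also act on transitions out of acute/chronic states
(recurrence); `run.effects_apply_to_recurrence: false` restricts them to
first events. Effects persist for as long as the strategy is active
(lifelong by default — the underlying trials ran 2 and 5.6 years, so this
is an extrapolation the lifetime horizon forces).

**Adherence** is a piecewise-constant adherent fraction by years since
start (the drug variant: 75% for years 0–5, 50% after). It is applied as an
exact mixture in probability space — `p' = f·p(HR) + (1−f)·p` — rather than
as an averaged HR, and only to the drug component of the combination (salt
substitution is household-level). For the pooled direct-HR variant the
evidence HR is applied as-is (no rescaling to the trial δ); a
`delta_sbp_mmhg` can be set on the component to rescale it instead.

## Accounting

Costs and utilities accrue on the **post-transition occupancy** of each
cycle, so one acute-state cycle carries exactly one acute cost and newly
dead members accrue nothing. Discounting is 5%/year for both costs and
QALYs, end-of-cycle by default (`(1+r)^−(t+1)`; start-of-cycle available).
No half-cycle correction by default; `run.half_cycle_correction: true`
averages pre- and post-transition occupancy as a results-sensitivity knob.
Intervention cost accrues on all alive states while the strategy is active
(switchable to disease-free only). The utility of untreated disease-free is
pinned to 1 and death to 0; monetary inputs may be declared in RMB and are
normalized at 6.9 RMB/USD (2019).

Event counting: the headline "CVD events" measure is cumulative
**first**-event incidence — the flow out of `disease_free` into any acute
state or directly to fatal CVD. Total acute-state entries (including
recurrences) are also tracked (`CohortTrace.total_acute_entries`) as the
alternative counting convention.

## Cost-effectiveness comparison

Strategies are compared on discounted lifetime totals. The efficient
frontier sorts by QALYs, removes strictly dominated strategies (no more
QALYs at no less cost), then iteratively removes extended-dominated ones
(ICER vs the previous frontier member exceeding the next member's) until
frontier ICERs strictly increase. Negative ICERs are never reported as
ratios; cost-saving and dominated pairs get labels (`classify_pair`). The
decision at a WTP threshold walks the frontier and is provably equivalent
to the net-monetary-benefit argmax (asserted against brute force on random
strategy sets). Threshold search inverts a monotone parameter→ICER map by
bisection to 0.1% of the WTP.

## Sensitivity analysis

One-way analysis re-runs the ICER with each parameter at its low/high bound
(all else at base) and sorts by spread; bounds that make the model invalid
are recorded as failed cells, not raised.

PSA families follow the standard CEA convention by parameter domain:
beta for probabilities and utilities, gamma for costs, lognormal for hazard
ratios, uniform as fallback. Hyperparameters are fit by anchoring the mean
(median for lognormal, i.e. the geometric-mean convention) at the base
value and matching low/high to the 2.5/97.5 percentiles via a
one-dimensional quantile fit; degenerate ranges become point masses and
infeasible fits fall back to uniform with a warning. Parameters are sampled
jointly and independently (no correlation structure is specified); draw
order is fixed by sorted parameter path, so a seed fully determines the
run. Invalid draws are resampled (warning above a 1% rate). CEACs report,
per WTP grid point, the fraction of iterations in which each strategy
maximizes NMB, with exact ties split equally, so probabilities partition
to 1.

## Synthetic study conditions

Real transition probabilities and hazard ratios derive from a restricted
cohort, so the generator (`bpcea.synthetic`) emulates their structure with
documented calibration constants (top of the module), chosen once so that
the defaults land in realistic territory: lifetime discounted QALYs ≈ 15.7
from age 40, salt-substitution ICER in the low thousands of USD/QALY, drug
treatment extended-dominated overall, and the combination becoming
affordable at the GDP threshold only in the high-CVD-risk variant.
Structural invariants are enforced by construction per seed: first-event
probabilities strictly increase across age bands (jittered base × gradient,
gradient > 1); the excess (1−HR) shrinks geometrically with age (factor
0.55/band) and hemorrhagic stroke is clamped to the strongest HR per band;
acute utility ≤ chronic utility; every generated set passes the loader's
schema. The high-risk variant scales all baseline CVD hazards by a
rate-domain multiplier (default 2.0).

What the generator does **not** emulate: correlated parameter uncertainty,
cohort heterogeneity within an age band, secular trends in event rates or
costs, treatment side-effects, and very-old-age mortality beyond the last
band. Passing tests therefore demonstrate correctness of the machinery and
the qualitative orderings (age and risk-group gradients), not agreement
with any real population's ICER values.

Analytic toy fixtures (`generate_toy_fixture`) collapse the state space to
an effective two- or three-state chain whose discounted totals have
geometric/annuity closed forms; the engine is verified against these to
1e-9 and against exhaustive path enumeration on short horizons.

## Problem sizes

Default runs simulate up to 60 annual cycles (age 40→100) and take
milliseconds per strategy. The shipped acceptance run uses 1000 Monte Carlo
iterations per PSA and 1000-model property sweeps, keeping the whole
verification under a minute on one CPU; PSA iteration counts are a single
argument (`--n` on the CLI, `n_iterations` in `psa`) for larger runs.

## Known limitations

* Annual cycles cannot represent sub-annual event sequences; the acute
  stage is exactly one cycle.
* Constant extrapolation beyond age 75 understates old-age mortality, which
  inflates absolute QALYs for all strategies (differences are less
  affected).
* Utilities are time-invariant per state; comorbid/recurrent disease reuses
  the single chronic utility of the current event type.
* BP effects are extrapolated beyond trial duration for the lifetime of the
  strategy (an effect-duration cap is a config option).
* No budget impact, equity weighting, or EVPI; plotting is out of scope
  (CEAC/tornado tables export as CSV).
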