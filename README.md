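# bpcea

Markov cohort cost-effectiveness modelling of blood-pressure-lowering
interventions in prehypertensive adults.

## The problem

Adults with prehypertension (blood pressure 130–139/80–89 mm Hg) face an
elevated lifetime risk of cardiovascular disease (CVD). Two primary-prevention
options lower their systolic blood pressure (SBP): replacing household salt
with a potassium-enriched substitute (≈2 mm Hg reduction) and antihypertensive
drug treatment (≈5.6 mm Hg). Which option — or their combination — is worth
paying for, for whom, and from what age, is a health-economic question.
`bpcea` is a library for answering it with a decision-analytic Markov cohort
model, aimed at health economists and epidemiologists who want every stage of
such an analysis — cohort simulation, effect translation, cost-effectiveness
comparison, sensitivity analysis — as tested, composable Python.

## The model

A cohort starts disease-free at a chosen age and moves through annual cycles
over health states: disease-free; acute and chronic stages of four nonfatal
event types (acute myocardial infarction, other ischemic heart disease,
ischemic stroke, hemorrhagic stroke); and two absorbing states (fatal CVD,
non-CVD death). Acute states are one-cycle tunnels carrying hospitalization
costs. Baseline inputs are 10-year cumulative transition probabilities by age
band (35–44 … 65–75), converted to annual probabilities by
`r = 1 − exp(ln(1 − p)/10)`.

Intervention effects enter as hazard ratios. Evidence gives an HR per
reference SBP reduction (e.g. per 10 mm Hg, varying by outcome and age band);
under the standard log-linear assumption an intervention reducing SBP by δ
acts with `HR^(δ/ref)`, combinations multiply their components' HRs, and
multipliers are applied to probabilities in the rate domain,
`p' = 1 − (1 − p)^HR`. Partial adherence mixes treated and untreated
probabilities.

Each cycle accrues costs (state costs plus intervention cost on alive states)
and utility-weighted life-years, discounted at 5%/year. Strategies are
compared on discounted lifetime totals: incremental cost-effectiveness ratios
(ICERs), the efficient frontier with simple and extended dominance, and a
decision at a willingness-to-pay (WTP) threshold — by default US$10,264.8 per
QALY, the 2019 Chinese GDP per capita — equivalent to maximizing net monetary
benefit `WTP·QALY − cost`. One-way sensitivity produces tornado tables;
probabilistic sensitivity analysis (beta/gamma/lognormal parameter
distributions, Monte Carlo) produces cost-effectiveness acceptability curves.

Because the cohort data behind the original transition probabilities are
restricted, the package ships a synthetic parameter generator that reproduces
their statistical structure (probabilities rising with age, HRs attenuating
with age and strongest for hemorrhagic stroke, acute/chronic cost split) so
the whole pipeline runs and is tested without any external data.

## Worked example

```python
from bpcea import Model, SyntheticSpec, decide, generate_parameter_set, validate_config

cfg = validate_config(generate_parameter_set(SyntheticSpec(seed=1, start_age=40.0)))
model = Model(cfg)
for r in model.strategy_results():
    print(f"{r.name:<20}{r.total_cost:>10.2f}{r.total_qaly:>9.3f}")
frontier = model.frontier()
print(decide(frontier, model.decision_settings()).name)
```

prints

```
none                   1464.08   15.720
salt_substitution      1558.51   15.736
drug_treatment         2537.43   15.763
combination            2637.00   15.776
salt_substitution
```

Reading the numbers: the combination strategy gains the most QALYs (15.776 vs
15.720 untreated) but at the highest cost. On the efficient frontier, salt
substitution costs $5,814 per QALY gained over no intervention — below the
$10,264.8 WTP threshold, so it is adopted — while the next frontier step
(combination, $26,616/QALY) and drug treatment alone (extended-dominated) are
not cost-effective for the overall prehypertensive population. The
`examples/` directory has one short script per capability: strategy runs,
effect translation, tornado tables, PSA/CEAC, and threshold search (e.g. the
salt-substitute price at which its ICER reaches the threshold: $12.84/year
under the synthetic defaults).

A thin CLI mirrors the library: `bpcea synth`, `bpcea run`, `bpcea owsa`,
`bpcea psa`, `bpcea ceac`, `bpcea threshold` (see `bpcea --help`). Parameter
files are YAML/JSON with schema validation; monetary fields may be declared
in RMB and are normalized to USD at 6.9 RMB/USD.

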