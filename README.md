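# fishcards

A headless, scriptable implementation of the **Fishing Cards**
common-pool-resource (CPR) game, with programmable participant agents, a
synthetic-cohort generator, and the mixed-model analysis pipeline used to
quantify sustainable harvesting behavior.

## The problem

How do people moderate their harvesting when a shared, renewable resource
becomes limited? Fishing Cards operationalizes this as a two-phase game:
in **Phase 1** fish are unlimited and the player simply must not let fish
escape (three hearts); in **Phase 2** a green bar (0–100 %) represents the
shared stock — every hit drains it (rod card −5 pp, radar card −15 pp),
two automated submarines drain 10 pp per capture at a pace that mirrors
the player's own inter-response times (IRTs), and the bar regenerates
+5 pp every 2 s. Reaching 0 % is defeat; ten consecutive undefeated 40 s
rounds win the phase. The sustainable regimes are slow pacing and the
low-extraction card: regeneration supplies 2.5 pp/s, two slow submarines
take 1.67 pp/s, leaving the player a budget of ~0.8 pp/s.

The package is aimed at behavioral researchers who want to (a) run the
game mechanics exactly and deterministically from code, (b) generate
synthetic cohorts with controllable effect structure, and (c) run the
statistical analysis end to end.

## The statistical core

Three questions ("objectives") are answered with generalized linear mixed
models with crossed random intercepts for participant *i* and response
index *r*:

1. **Pace:** IRT ~ Phase (gamma family, inverse/identity links):
   `g(E[IRT]) = β₀ + β₁·Phase2 (+ age terms) + uᵢ + vᵣ`
2. **Choice:** P(radar) ~ Phase × Age (Bernoulli, logit/probit links)
3. **Resource feedback:** P(radar) ~ bar level at choice, Phase-2 rows
   only.

For each objective a grid of six specifications is fitted and the
lowest-AIC converged model selected. The fitter (Laplace approximation,
joint penalized-likelihood mode, Schur-complement elimination of the
response-index block) is implemented in `fishcards.glmm` and cross-checked
against `lme4::glmer` in the test suite. Marginal means are
back-transformed from the link scale with delta-method 95 % CIs.

## Worked example

```bash
python examples/03_objectives.py
```

generates a default synthetic cohort (12 teenagers, 18 adults, seed 42),
runs the pipeline, and prints:

```
=== Objective 1: selected obj1: phase + age [gamma/inverse] (AIC 16818.3) ===
           estimate  std_error  statistic  p_value
intercept    0.1858     0.0046    40.7498   0.0000
phase2      -0.0890     0.0026   -34.1095   0.0000
age_adult   -0.0086     0.0054    -1.5827   0.1136
marginal means:
 phase  estimate  ci_low  ci_high
     1    5.5086  5.3236   5.7069
     2   10.8074 10.1895  11.5051
```

The negative `phase2` estimate on the inverse-link scale means a *longer*
IRT: the back-transformed marginal pace slows from ≈5.5 s to ≈10.8 s per
response under limited resources. Objective 2 selects the interaction
model (`phase2 −1.57`, `phase2:age_adult −1.03`, both p < 0.001): radar
use drops from ~62 % to ~25 % for teenagers and from ~64 % to ~12 % for
adults. Objective 3 finds a positive resource slope (0.015 logit per
percentage point, p = 0.003): the fuller the bar, the likelier the
high-extraction card.

Other entry points: `examples/01_single_game.py` (single Phase-2 attempts,
sustainable vs depleting pace), `examples/02_cohort_records.py` (response
records and per-phase summaries), `examples/04_sustainability.py` (the
2.5 pp/s threshold), and a CLI:

```bash
fishcards simulate --phase 2 --seed 1 --out events.csv --irt 12
fishcards cohort   --seed 1 --out records.csv
fishcards analyze  --records records.csv --out report/
fishcards pipeline --seed 1 --out run/          # everything, deterministic
```

Event logs are plain CSV (one row per simulator event, seconds with one
decimal); a pipeline run writes a manifest with per-output SHA-256 so that
identical (config, seed) pairs are byte-identical.

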