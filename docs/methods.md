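# Methods

## The model

`adhertraj` implements the standard two-stage analysis of longitudinal
medication adherence from pharmacy dispensing data.

**Stage 1 — adherence measurement.** For each patient, the proportion of
days covered (PDC) is computed for each of `T` consecutive fixed-length
periods (default 12 × 30 days). A fill covers `days_supply` consecutive
days from its fill date; an early refill is *banked*: its coverage starts
the day after the previous supply runs out, the standard same-drug
convention for PDC. Supply dispensed before the window contributes its
overhang (carry-in). Period `t` is scored adherent when PDC_t ≥ 0.8, with
the boundary inclusive. Only the binary indicators `y_it ∈ {0,1}` enter
stage 2.

**Stage 2 — group-based trajectory model.** A finite mixture of logistic
regressions on polynomial time:

    P(y_i) = Σ_g π_g Π_t p_gt^{y_it} (1 − p_gt)^{1−y_it},
    logit p_gt = β_g0 + β_g1 t + β_g2 t² [+ β_g3 t³],   t = 1..T (raw),
    π = softmax(0, θ_2, ..., θ_G).

Maximum likelihood is obtained by multi-start EM. The E-step computes
posterior responsibilities; the M-step reduces, because `p_gt` depends on
time only, to one *aggregated* binomial logistic regression per group on
`T` period-level sufficient statistics (weighted successes `Σ_i r_ig y_it`
out of `Σ_i r_ig` trials), solved by Newton ascent with step-halving and
projection into the coefficient box `|β| ≤ 15`. A rejected step leaves the
parameters unchanged (a generalized M-step), so the EM log-likelihood is
monotone by construction even when the box binds. The best start is run to
convergence (relative log-likelihood change < 1e-8, ≤ 500 iterations) and
then polished by bounded L-BFGS-B on the full parameter vector, using the
exact gradient from Fisher's identity. Groups are then put in canonical
order — descending mean fitted adherence over `t = 1..T` — which resolves
label switching deterministically; group 0 is always the most adherent
trajectory.

**Model selection.** Candidates over 2–5 groups and polynomial orders
{2, 3} are ranked by BIC, reported in both conventions
(−2·logL + k·log N, minimised; and logL − (k/2)·log N, maximised — the two
orderings are identical, and reporting both removes any ambiguity about
which column a reader minimises "in absolute value"). Candidates whose
smallest hard-assigned group falls below 5% of the cohort are disqualified
before BIC ranking. Clinical relevance is deliberately *not* automated:
the selection trace lists every candidate with its BIC, group shares and
disqualification reason so an analyst can override.

**Adequacy.** Nagin's diagnostics on the selected model:
AvePP_g (mean posterior of group g among subjects assigned to g; adequate
at ≥ 0.7) and OCC_g = [AvePP_g/(1−AvePP_g)] / [π_g/(1−π_g)] (adequate at
≥ 5). The report also shows the π̂-vs-assigned-share gap as informational
output.

**Predictors.** Group differences are screened by Pearson chi-square
(categorical) and one-way ANOVA (continuous), then modelled jointly by a
multinomial logistic regression of hard assignment on all covariates
simultaneously, with the adherent group as the reference outcome.
Inference is Wald (OR, 95% CI, p), with no multiplicity adjustment —
matching how such tables are conventionally reported. Classification error
in the hard assignments is not propagated (no three-step correction); with
the adequacy levels the synthetic cohorts reach (AvePP > 0.9) the
attenuation is negligible, but this is a known limitation for poorly
separated data.

## The synthetic-data generator

The generator emulates a single-centre oral-endocrine-therapy cohort:
~350 patients, 12 consecutive 30-day periods, a 90-day pre-window lookback.
It draws, in order: binary covariates (independent Bernoulli; defaults
diabetes 0.335, hypertension 0.578, depression 0.153), latent group
membership (multinomial logit), monthly adherence indicators
(Bernoulli(p_gt)), and finally a refill stream *consistent* with each
month's indicator.

Default trajectory groups (shares 0.439 / 0.255 / 0.306):

| group            | β (order 2)            | shape                  |
|------------------|------------------------|------------------------|
| adherent         | (3.0, 0.05, −0.01)     | flat, ≈ 0.95           |
| gradual_decline  | (3.2, −0.25, −0.015)   | 0.95 → 0.12            |
| improving        | (−2.6, 0.45, −0.012)   | 0.10 → 0.75            |

The betas are not estimates of any real cohort — no study prints them —
they are chosen so the three shapes are clearly separated, which is the
regime the adequacy thresholds (AvePP ≥ 0.85, OCC > 5) describe.

Membership covariate effects default to diabetes log-OR log(2.96) toward
the declining group and log(1.40) toward the improving group, hypertension
log(1.32)/log(1.82), depression null. Because positive shifts would
otherwise inflate the non-reference groups' marginal shares, the intercepts
are *calibrated* by a fixed-point iteration (exact expectation over the
2^C covariate patterns) so the marginal mixing proportions equal the
specified shares while the conditional effects stay exactly as given.

Fill materialisation guarantees the round-trip contract
`binarize(PDC(emit_fills(v))) == v` for every binary vector `v`, under all
noise processes, by construction: adherent months get a 30-day fill
jittered ≤ L/5 days from the month start (under banked chaining the
overhang into the next month is the maximum jitter, so coverage never
drops below 0.8·L); non-adherent months get no fill or a short partial
fill (supply ≤ L/3, start ≤ L/6) whose coverage including overhang stays
strictly below 0.8·L; month 1 may be served by a carry-in fill dated up to
L/5 days before the window; an exhausted "stale" fill from ≥ 2L days back
exercises window clipping without covering anything.

What the generator does **not** emulate: death, censoring or mid-window
therapy initiation (every patient is observed for all 12 periods), dose
changes, switching between agents, 60/90-day fills, seasonal refill
behaviour, or covariate correlation. Passing tests therefore demonstrate
correctness of the *machinery* under the stated data-generating process,
not robustness to the messiness of real dispensing extracts.

## Numerical choices

- Coefficient box |β| ≤ 15 on the logit scale keeps perfectly separated
  groups finite (p within ~3e-7 of 0/1 at t=1).
- 20 random starts by default (one deterministic quantile start — subjects
  sorted by mean adherence and split into contiguous blocks — plus
  Dirichlet(0.3) responsibility draws); each start gets a 60-iteration EM
  burn-in before the best continues.
- Hard assignment is argmax of the posterior; ties (measure zero) resolve
  to the lowest canonical group index.
- Mixing proportions are floored at 1e-12 inside EM for log-stability; a
  group below 1e-8 raises a degenerate-fit warning, not an error.
- `binarize` compares with `>=` on IEEE doubles; period PDCs are exact
  multiples of 1/L, and k/L for k = 0.8·L rounds to the same double as 0.8,
  so the boundary behaves exactly.

## Parameter recovery: what is checked

Recovery tests compare fitted mixing proportions to each simulated
cohort's *realized* latent composition rather than the population
proportions: at N = 350 the multinomial sampling noise of the composition
itself (SE ≈ 0.027 per group) is of the same order as the ±0.05 recovery
band, so the realized composition is the parameter a single cohort
identifies. Across 20 default cohorts the fitted proportions land within
0.05 of the realized composition in every seed, and the fitted group
curves stay within 0.1 of the generating curves pointwise.

## Problem sizes

Default analyses run at the emulated study scale — 350 patients × 12
periods, 2–5 group grid, 20 starts (≈ 3 s end to end). The test suite uses
the same scale for acceptance-style checks and smaller cohorts (60–350
patients) for unit-level properties; coverage calibration uses 200
replicates at N = 350.

## Known limitations

- Single shared polynomial order across groups per fit (per-group orders
  are not supported).
- No covariates inside the membership model during trajectory fitting;
  predictors are assessed post hoc on hard assignments.
- Wald CIs are mildly anti-conservative at moderate N; the calibration
  test accepts 90–98% empirical coverage at N = 350.
- The whole-window PDC (`overall_pdc`) is covered-days/window-length, used
  only for the trajectory-vs-binary discordance report.
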