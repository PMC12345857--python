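# adhertraj

Group-based trajectory modelling of medication adherence from pharmacy
dispensing records.

Longitudinal adherence to a chronic oral therapy (the motivating setting is
adjuvant oral endocrine therapy in hormone-receptor-positive breast cancer)
is usually summarised by a single proportion of days covered (PDC) over a
year, which hides *when* and *how* patients become non-adherent. This
package implements the trajectory alternative end to end, for
pharmacoepidemiologists and health-services researchers working with refill
data:

1. **PDC panel** — dispensing records (patient, fill date, days supply) →
   monthly PDC over 12 consecutive 30-day periods, with banked-supply
   overlap adjustment and pre-window carry-in, binarised at PDC ≥ 0.8;
2. **Trajectory model** — a finite mixture of logistic regressions of the
   monthly indicator on polynomial time,
   `logit p_gt = β_g0 + β_g1 t + β_g2 t²`, with mixing proportions
   `π = softmax(0, θ)`, fitted by multi-start EM + quasi-Newton polish;
3. **Selection and adequacy** — the 2–5 group grid ranked by BIC (both
   sign conventions reported) with a 5% minimum-membership rule, validated
   by Nagin's criteria: average posterior probability of assignment
   (AvePP ≥ 0.7) and odds of correct classification
   `OCC_g = [AvePP_g/(1−AvePP_g)] / [π_g/(1−π_g)]` (≥ 5);
4. **Predictors** — chi-square/ANOVA bivariate screens and a multinomial
   logistic regression of trajectory membership on covariates with the
   adherent group as reference (adjusted ORs, Wald 95% CIs);
5. **Synthetic cohorts** — a generator that simulates dispensing streams
   from a fully specified trajectory model, so every stage is testable
   without patient-level data (which, for the motivating cohorts, is never
   public).

See `docs/methods.md` for the model, the generator's guarantees, and the
numerical choices.

## Worked example

```python
import numpy as np
from adhertraj import synthetic, pdc, gbtm, selection

# a 350-patient synthetic cohort: 3 trajectory shapes, monthly refills
spec = synthetic.CohortSpec(n_patients=350, seed=42)
cohort = synthetic.sample_cohort(spec)                    # 3402 records

panels = pdc.build_panels(cohort.records, synthetic.ANCHOR_DATE,
                          cohort.patient_ids)
panel = pdc.binary_matrix(panels)                         # 350 x 12 binary

grid = selection.fit_grid(panel, groups=range(2, 6), orders=(2,),
                          n_starts=20, seed=42)
model, trace = selection.select_model(grid)
print(trace[["n_groups", "bic_neg2", "min_assigned_prop",
             "qualified", "selected"]].to_string(index=False))

post = gbtm.posterior(model, panel)
print(selection.adequacy_report(model, post)
      [["group", "pi_hat", "assigned_prop", "avepp", "occ"]]
      .round(3).to_string(index=False))
```

Output:

```
 n_groups    bic_neg2  min_assigned_prop  qualified  selected
        2 4321.457459           0.297143       True     False
        3 3998.983675           0.245714       True      True
        4 4018.058627           0.017143      False     False
        5 4037.793066           0.011429      False     False
 group  pi_hat  assigned_prop  avepp     occ
     0   0.458          0.460  0.972  40.859
     1   0.247          0.246  0.954  63.067
     2   0.295          0.294  0.996 529.390
```

Reading this: the 3-group candidate wins on BIC among models meeting the 5%
minimum-membership rule (the 4- and 5-group fits each produce a group
holding under 2% of patients and are disqualified). Group 0 is the
persistently adherent trajectory (canonical ordering is by descending mean
fitted adherence), group 1 the gradual decline, group 2 the improving
pattern; the estimated mixing proportions recover the generating split
(0.44/0.26/0.31) to within sampling noise. Every group clears the adequacy
bars comfortably — AvePP ≥ 0.95 against the 0.7 criterion, OCC ≥ 41 against
the 5 criterion — so patients are classified essentially without ambiguity.

The same analysis runs from the shell:

```bash
adhertraj simulate --seed 42 --out cohort/
adhertraj pdc --records cohort/dispensing.csv --start 2022-01-01 --out panel.csv
adhertraj select --panel panel.csv --groups 2:5 --orders 2 --seed 42 --out fit/
adhertraj run --out results/        # full pipeline in one step
```

`adhertraj run` additionally writes per-patient assignments, the
Table-1/Table-2-style predictor CSVs, figure data (predicted and observed
adherence per group per period), and a manifest with the seed and config
hash for reproducibility.

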