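# cesofa

Derivation and validation of a **cardiac-extended SOFA score (CE-SOFA)**
for 30-day mortality prediction in sepsis.

The SOFA score sums six organ-system sub-scores (0–4 points each, total
0–24). Its cardiovascular component — mean arterial pressure plus vasoactive
therapy — does not register myocardial injury, dysfunction or arrhythmia.
`cesofa` implements the full statistical pipeline for extending SOFA with
ordinal points for high-sensitivity cardiac troponin T (hs-cTnT),
NT-proBNP, and atrial fibrillation (AF):

1. **Screening** — nine continuous cardiovascular variables (hs-cTnT,
   NT-proBNP, HR, SBP, DBP, MAP, PP, RPP, PPP; biomarkers on the log scale)
   are modelled against 30-day mortality with natural-cubic-spline logistic
   regressions, spline flexibility chosen by AIC, variables ranked by AUC.
2. **Ordinalization** — retained variables become 0–4 point groups whose
   cut-offs are placed so adjacent bins carry approximately equal
   log-odds increments ("balanced effect size"); AF maps to a binary
   2-point scheme.
3. **Substitution models** — the six-component multivariable logistic model
   of mortality is refitted with the cardiovascular sub-score replaced by
   each point group (odds ratios per point, Wald 95% CIs).
4. **Extension and selection** — every weighted combination of point groups
   (single/double/triple points) extends the base score; candidates are
   ranked by training AUC and the leaders compared against base SOFA with
   the paired DeLong test and the category-free Net Reclassification
   Improvement (NRI).
5. **Validation** — the selected model is evaluated on a held-out cohort:
   AUC with DeLong CI, DeLong comparison, NRI, and quintile calibration
   with the Hosmer-Lemeshow test.

The default CE-SOFA composition is SOFA + hs-cTnT-points (0–4) +
NT-proBNP-points (0–4) + double AF-points (0 or 4), range **0–36**.

All inferential machinery — logistic maximum likelihood (IRLS), the
midrank Mann-Whitney AUC with DeLong placement-value variances, the paired
DeLong test, continuous NRI, Hosmer-Lemeshow, and a Hanley-McNeil /
Monte-Carlo AUC sample-size calculation — is implemented from first
principles and cross-checked against independent oracles in the test suite.

Because no patient-level cohort is distributed, the package ships a
**synthetic sepsis cohort generator** that emulates a vasopressor-dependent
sepsis population (log-normal biomarkers, ~35% AF, SOFA ≈ 8–9, ~31%
30-day mortality) with a logistic outcome model acting through the point
groups, so every stage of the pipeline is testable end to end with a known
generative truth.

## Worked example

```python
from cesofa import (GeneratorConfig, generate_cohort, split_cohort,
                    ScoreDerivation, ScoreEvaluation, BASE_SOFA)

cohort = generate_cohort(GeneratorConfig(n=503, seed=7), label="demo")
train, test = split_cohort(cohort, n_train=250, seed=7)

results = ScoreDerivation(train).fit()        # steps 1-4 on the training half
report = ScoreEvaluation(test, results.final_model, baseline=BASE_SOFA).fit()
print(report.summary())
```

or equivalently from the shell:

```bash
cesofa demo --seed 7 --outdir demo_out
```

which prints (stderr log elided):

```
Evaluation of 'SOFA+afx2+hs_ctntx2+nt_probnpx2' on cohort 'demo/test' (n = 253, mortality = 29.6%)
  SOFA+afx2+hs_ctntx2+nt_probnpx2: AUC 0.744 (95% CI 0.680-0.809)
  SOFA: AUC 0.573 (95% CI 0.498-0.647)
  DeLong: AUC 0.744 vs 0.573, z = 4.345, p = 0.0000
  NRI 0.8262 (events +0.4667, non-events +0.3596), p = 0.0000
Calibration (predicted-risk quantile groups):
     mean_predicted  observed   n  events  expected  ci_low  ci_high
  0          0.0765    0.0893  56       5    4.2857  0.0387   0.1926
  1          0.1788    0.1556  45       7    8.0453  0.0775   0.2878
  2          0.2910    0.2794  68      19   19.7874  0.1868   0.3956
  3          0.4181    0.4571  35      16   14.6345  0.3047   0.6181
  4          0.5765    0.5714  49      28   28.2470  0.4327   0.6998
  Hosmer-Lemeshow chi2 = 0.563, df = 3, p = 0.9050
```

Reading: on this synthetic test cohort the derived extension (here with
double biomarker points and double AF points) discriminates 30-day
mortality clearly better than base SOFA (AUC 0.74 vs 0.57; DeLong
p < 0.001; NRI +0.83), and its predicted risks track the observed
proportions across the five risk quintiles (Hosmer-Lemeshow p = 0.91,
i.e. no evidence of miscalibration). Synthetic effect sizes are
deliberately strong, so the AUC gap is larger than one should expect on
real cohorts.

The `demo` output directory contains the cohort CSVs, the derivation
report (`derivation.json`), the selected model (`ce_sofa_model.yaml`,
reusable with `cesofa score`/`cesofa evaluate`), the evaluation reports,
and provenance sidecars recording the seed and configuration. Subcommands
`simulate`, `split`, `derive`, `score` and `evaluate` expose the stages
individually (`cesofa --help`).

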