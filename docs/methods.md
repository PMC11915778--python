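# Methods

This note documents the statistical models, algorithms and design choices
behind `cesofa`, the parameters that matter, and what the synthetic-data
pipeline does and does not establish.

## Scores

**Base SOFA.** The total SOFA score is the sum of six organ-system
sub-scores, each an integer 0–4 (range 0–24). Five sub-scores
(neurological, respiratory, renal, hepatic, coagulation) are taken as
recorded. The cardiovascular sub-score is always *recomputed* from mean
arterial pressure (MAP = DBP + (SBP − DBP)/3) and vasoactive therapy with
the original tier table: 0 if MAP ≥ 70 mmHg without agents; 1 if MAP < 70;
2 for dopamine ≤ 5 µg/kg/min or dobutamine at any dose (the
`other_vasoactive` flag); 3 for dopamine > 5 or norepinephrine ≤ 0.1;
4 for dopamine > 15 or norepinephrine > 0.1; the highest applicable tier
wins. Other pressor dialects (epinephrine, vasopressin) should be mapped
onto the norepinephrine tier by dose upstream. Recomputing rather than
storing the sub-score guarantees consistency with the pressure fields.

**Point schemes.** An ordinal point scheme maps one variable to weighted
points: a continuous variable is binned by ascending thresholds
(left-closed: a value equal to a threshold enters the upper bin — the
boundary convention is not standardized, so it is fixed and documented
here), giving base points 0..k; binary AF gives a fixed 2 points when
present; an integer weight ∈ {1,2,3} multiplies the base points. The
`transform` field records the scale on which thresholds were derived; the
binning itself is performed on the original scale, which is equivalent
because the log is strictly increasing.

**CE-SOFA.** The shipped default model is SOFA + hs-cTnT-points (0–4) +
NT-proBNP-points (0–4) + double AF-points (0 or 4), range 0–36. Its
biomarker thresholds are *synthetic defaults* — the 20/40/60/80% quantiles
of the generator's log-normal biomarker distributions (hs-cTnT 18/37/68/137
ng/L; NT-proBNP 1540/3500/7130/16230 ng/L) — intended for score arithmetic
and simulation studies. For real data the thresholds must be re-derived on
a training cohort with the derivation pipeline. The hs-cTnT ≥ 15 ng/L
"elevated" flag is a clinical annotation only, never a score cut-off.

## Synthetic cohort generator

The generator emulates a vasopressor-dependent sepsis cohort:

- **Biomarkers**: log-normal; hs-cTnT median 50 ng/L with log-SD 1.2,
  NT-proBNP median 5000 ng/L with log-SD 1.4. The log-SDs are
  back-computed from survivor/non-survivor interquartile ranges of such
  cohorts assuming log-normality (log-IQR width / (2 × 0.6745)); only
  medians and IQRs are typically reported, so pooled dispersion is a
  modelling choice recorded in the provenance sidecar. Values are floored
  at assay detection limits (3 and 5 ng/L) to keep log transforms finite.
- **Vitals**: HR ~ N(100, 20²) clipped to [30, 220]; SBP ~ N(110, 18²) and
  DBP ~ N(60, 10²) with redraws enforcing DBP + 5 < SBP (a mild truncation
  of the nominal marginals). All patients carry a norepinephrine dose
  (log-normal, median 0.18 µg/kg/min) — the emulated population is
  pressor-dependent by inclusion, which pins the cardiovascular SOFA
  sub-score at 3–4 for most patients.
- **AF**: Bernoulli with prevalence 0.35, split 60/40 between pre-existing
  and new-onset; the two levels are retained in the data model but
  collapsed into a single binary predictor in every analysis.
- **SOFA sub-scores**: each of the five recorded components i.i.d. from a
  per-component distribution over {0..4} (default mass 0.45/0.25/0.15/
  0.10/0.05, giving total SOFA ≈ 8–9 with SD ≈ 2.7).
- **Outcome**: 30-day death from a logistic model whose linear predictor
  acts through the *point groups* of the scoring module — per-point
  log-odds for the five sub-scores (ORs 1.27–1.43), the computed
  cardiovascular sub-score (OR 0.85, reflecting its weak/inverse adjusted
  association in pressor-dependent cohorts), hs-cTnT-points (OR 1.88),
  NT-proBNP-points (OR 1.68), HR-points (OR 1.0, a null effect), and the
  AF indicator (OR 4.15). Routing the outcome through point groups rather
  than raw values makes downstream threshold recovery a well-posed
  exercise with a known truth.
- **Intercept calibration**: β₀ solves E[expit(β₀ + η)] = target mortality
  (default 0.31) by bisection to |Δ| < 10⁻⁴ on a fixed-seed calibration
  sample of 20 000 covariate draws; the expectation is monotone in β₀ so
  bisection always converges within the iteration cap.
- **Correlation hook**: covariates are independent by default (joint
  dependence is rarely reported); a user-supplied 5×5 correlation matrix
  over (log cTnT, log BNP, HR, SBP, DBP) is applied as a Gaussian copula
  for sensitivity analyses.

Everything is driven by `numpy.random.default_rng` streams derived from a
single seed; identical config + seed reproduces the cohort byte for byte.

**What passing tests show, and what they do not.** The generator matches
the marginal and multivariable *structure* of a real sepsis cohort, not
any particular dataset: covariates are (by default) independent, biomarker
effects are exactly ordinal through the generative thresholds, and there
is no measurement error, missingness, informative sampling or time
structure. Pipeline results on synthetic cohorts therefore demonstrate
correctness of the algorithms and estimators — recovery of a known truth —
not clinical performance. Synthetic effect sizes are strong, so AUC gaps
are larger than one should expect on real cohorts.

## Derivation pipeline

**Natural cubic splines.** The basis is the truncated-power natural-spline
construction: boundary knots at the data extremes, df − 1 interior knots at
equally spaced quantiles, df columns, linear beyond the boundary knots;
df = 1 degenerates to a single linear column. The test suite verifies span
equality with an independent construction (cardinal natural-spline
interpolants via `scipy.interpolate.CubicSpline`, natural boundary
conditions). Flexibility is chosen per variable by minimizing
AIC = 2k − 2·loglik over df ∈ {1,…,5} (unstated in most derivations; five
candidates cover linear through clearly flexible), ties broken toward the
smaller df.

**Screening.** Each of the nine cardiovascular variables is screened with
a spline-logistic fit of 30-day mortality; hs-cTnT and NT-proBNP enter on
the log scale (right-skewed); MAP, PP, RPP and PPP are computed on the fly
from SBP/DBP/HR. Discrimination is summarized by the AUC of the fitted
risk. Per-variable fit failures are reported inline without aborting the
screen.

**Ordinalization ("balanced effect size").** The published description —
cut-offs "strategically positioned to achieve balanced effect size" — does
not pin down an algorithm, and admits readings on the risk, odds or
ordinal-coefficient scale. It is operationalized here on the log-odds
scale: thresholds are chosen so the per-bin mean of the spline-fitted
log-odds rises by approximately equal increments. Concretely: thresholds
live on a 0.5%-quantile grid of the data, every bin must retain ≥ 5% of
observations, and coordinate descent minimizes

  var(adjacent-bin increments) − 10⁻³ · (last-bin mean − first-bin mean).

The small span bonus matters: when the true log-odds is linear in the
transformed variable, *every* threshold family has near-zero increment
variance (a one-parameter degenerate manifold), and pure variance
minimization stalls wherever it starts. The span term selects the
maximal-spread member of the family, whose outer bins sit at the bin-mass
floor — under a linear log-odds in log x this makes recovered thresholds
approximately geometric, as expected. Descent runs from two starts
(equal-mass quintiles, and outer bins at the mass floor) and keeps the
better optimum, since single-threshold moves cannot traverse the flat
manifold. The objective, grid resolution, mass floor and span bonus are
all exposed as parameters. Returned thresholds are always observed data
values, hence inside the data range.

**Bin counts.** Biomarkers use 5 bins (0–4 points); HR defaults to 3 bins
(0–2 points), matching its reported point range in the multivariable
table (its 0–4 description elsewhere is inconsistent; bin count is
configurable per variable). AF is binary with 2 base points.

**Substitution models.** Mortality is regressed on the five
non-cardiovascular sub-scores plus either the cardiovascular sub-score or
a candidate point group (odds ratios per point, Wald 95% CIs; optional
age/sex adjustment). HR is screened and ordinalized but excluded from
extension enumeration by default, mirroring its null adjusted effect in
the reference analysis; the exclusion is a constructor argument.

**Extension enumeration and selection.** Candidates are all models formed
by including each scheme at weight ∈ {1,2,3} (AF: {1,2}, matching the
published single/double AF points) or omitting it, excluding the empty
choice — 47 models for the default biomarker/AF set. Ranking is by
training AUC with ties broken toward fewer added maximum points
(parsimony) and then name; the top four get DeLong p-values and NRI
against base SOFA. Ranking is by AUC alone, with NRI/DeLong reported
rather than jointly optimized, matching the narrative order of the
reference derivation.

## Inference machinery

- **Logistic MLE**: IRLS with step-halving (guaranteeing a monotone
  non-increasing deviance trace), convergence at score max-norm < 10⁻⁸,
  100-iteration cap. Wald SEs from the inverse observed information.
  Separation is flagged (|coef| > 15 or a fitted probability within 10⁻¹⁰
  of 0/1) and affected confidence intervals reported as unbounded.
- **AUC**: midrank Mann-Whitney estimator — P(event > non-event) + ½
  P(tie) — with the DeLong placement-value variance for Wald CIs. Exactly
  invariant to strictly monotone score transformations.
- **DeLong test**: paired comparison via per-observation placement values;
  the variance of the AUC difference from empirical (co)variances of the
  placement components; two-sided normal p. Identical score vectors yield
  a zero-variance difference, reported as z = 0, p = 1 with a degeneracy
  flag rather than a division error.
- **NRI**: category-free (no risk categories are standard in this
  setting): event component P(up|event) − P(down|event) plus non-event
  component P(down|non-event) − P(up|non-event); any strict change in
  predicted risk counts. Asymptotic z from the standard multinomial
  variance of the two net components. A categorical variant with
  user-supplied thresholds is provided for completeness. Scores are
  converted to probabilities for the NRI and calibration analyses by a
  univariable logistic re-fit of the outcome on the composite score within
  the evaluated cohort.
- **Hosmer-Lemeshow / calibration**: groups by predicted-probability
  quantiles — quintiles by default, matching the five-group calibration
  display convention rather than deciles — with boundary ties collapsed
  deterministically into the lower group and emptied groups merged with a
  warning; χ² = Σ (O − E)²/(E(1 − E/n_g)), df = groups − 2; per-group
  observed proportions carry Wilson 95% intervals for the calibration
  curve.
- **Sample size for one ROC**: smallest n with power ≥ target for testing
  AUC = A₀ against truth A₁, via the Hanley-McNeil variance and the
  two-quantile condition (analytic), or by binary search over a binormal
  Monte-Carlo power estimate whose test statistic standardizes by the
  null-hypothesis SE (the classical single-ROC test; this also keeps the
  two methods consistent with each other). The event fraction enters
  through the allocation parameter. The required n diverges as A₁ → A₀,
  which is raised as an error.
- Two-sided tests and 95% intervals throughout.

## Numerical and degenerate-input conventions

Deterministic tie-breaks everywhere: AIC ties to smaller df, ranking ties
to parsimony then name, quantile-boundary ties to the lower group.
Single-class outcomes, rank-deficient designs, non-positive pulse
pressures, out-of-range sub-scores and negative doses raise validation
errors naming the offending field and row. The train/test split is a
seeded permutation; seeded reproducibility is the contract (the original
spreadsheet-based split of the reference cohort is not reproducible).

## Problem sizes

Defaults are chosen so the full pipeline is interactive: the demo cohort
is n = 503 split 250/253; statistical calibration checks use 2000
replicates (DeLong type-I error at n = 250), 100 replicates of n = 5000
(parameter recovery), 500 replicates of n = 2000 (Hosmer-Lemeshow null),
and 50 seeded end-to-end derivations; each completes in seconds to a
couple of minutes on one CPU.

## Known limitations

- The ordinalization objective is one defensible reading of "balanced
  effect size"; alternatives (equal observed-risk increments,
  ordinal-regression coefficient equality) would yield different
  thresholds. The implementation exposes its objective parameters rather
  than claiming uniqueness.
- The generator draws covariates independently by default and SOFA
  sub-scores i.i.d.; real organ dysfunctions cluster. The correlation hook
  covers only the five continuous covariates.
- Wald inference throughout; no profile-likelihood or exact intervals, and
  separation yields flagged unbounded intervals rather than penalized
  estimates.
- The analytic sample-size routine depends on the Hanley-McNeil
  exponential approximation; for designs far from binormality prefer the
  Monte-Carlo flag.
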