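# Methods

## The validation problem

A story-recall screening test credits 28 idea units with 0/1/2 points at
an immediate and a delayed administration (totals 0–56).  Validating
such a test against a memory-clinic cohort means answering four
questions: what counts as normal for a given age and education
(norms); how well the delayed total separates impaired from normal
subjects (discrimination); where to place the cutoff (operating point);
and what a positive or negative screen means at a given disease base
rate (predictive values).  `normscreen` implements each stage as a
library function and chains them in a reproducible pipeline.

## Operational classification

Diagnostic groups are operationalised from scale scores only:

| gate | rule |
|---|---|
| cognitively normal MMSE | MMSE strictly above an education-specific minimum: higher 26, middle school 23, primary 22, illiterate 19 |
| functional independence | ADL < 16 (higher ADL = more impaired) |
| depression gate | 17-item HAMD ≤ 12 |
| vascular gate | HIS ≤ 4 |
| staging | CDR 0 (normal), 0.5 with memory domain 0.5 (MCI), ≥ 0.5 (dementia track) |

NC requires CDR 0 + normal MMSE + independent ADL; MCI additionally
requires the CDR 0.5/memory 0.5 pattern and clean depression/vascular
gates; the dementia track requires below-normal MMSE, CDR ≥ 0.5,
impaired ADL and clean gates.  Imaging and clinician judgment cannot be
derived from a table, so the dementia-track label is `AD_candidate`,
not AD.  When no label fires, the excluded reason reports the first
failing gate in a fixed documented order (depression → vascular →
track-specific gates); the underlying criteria prescribe no order, so
one had to be chosen.

## Synthetic cohort generator

The generator exists so every downstream stage is testable without
patient data.  It emulates the published group-level structure of a
631-subject memory-clinic sample; the packaged default
(`data/table1.yaml`) encodes the five analysable groups (249 NC, 134
MCI, 97 AD, 14 vascular dementia, 50 other dementia; the two small
dementia groups reuse the pooled all-dementia moments since no separate
ones are published).

**Bounded score marginals.**  Group recall scores are drawn from a
truncated normal on [0, 56] whose *latent* parameters are solved
numerically so the truncated mean/SD hit the targets to 1e-6
(`solve_truncnorm`).  Feasibility matters: truncated normals are
log-concave, and a log-concave variable bounded below cannot have SD
exceeding its distance from the floor (the truncated-exponential
frontier).  Severely impaired groups print exactly such moments
(e.g. 1.60 ± 4.58) — a floor effect no truncated normal reproduces — so
`solve_truncnorm` raises a feasibility error and the generator falls
back to a zero-inflated floor mixture: a point mass at 0 with weight
1 − p plus a truncated-normal component with mean m₁ and SD m₁/2, where
m₁ = (s² + m²)/(1.25 m) and p = m/m₁ match the target mean and SD
exactly.  Clinically this reads as "most severe patients recall
nothing; a minority recall a moderate amount", which is how floor
effects actually arise.  Scores are rounded to integers and clipped to
[0, 56]; rounding perturbs moments by well under 0.05 score units and
is accepted rather than over-fitting a discrete distribution.

**Control-group demographic model.**  When a norming regression is
configured, NC delayed recall is generated as
`31.535 + 0.746·education − 0.206·age + N(0, σ)` with
σ = √(8.49² − (0.746·3.30)² − (0.206·8.87)²) ≈ 7.92, so the marginal SD
matches the published 8.49 and the published R² (≈ 13%) emerges by
construction.  The model-implied NC mean (≈ 27.4) differs from the
published group mean (26.60) by 0.8 points — the source's own
regression and group table are mutually inconsistent at that level, and
the regression is taken as generative truth for the control group.

**Demographics.**  Age and education are drawn independently (no
covariance is published), rounded to whole years, and clipped to
plausible ranges (50–85 and 0–25).  Education level is derived from
years (0 illiterate, 1–6 primary, 7–12 middle, ≥ 13 higher).

**Dependence structure.**  ISR, MMSE and the retest score couple to the
standardized DSR signal through a Gaussian copula.  The MMSE loading is
calibrated so that the *pooled* MMSE–DSR partial correlation (given age
and education) over the core NC/MCI/AD sample equals a configurable
target (default 0.575).  Pooled correlation is dominated by
between-group separation, so the calibration builds the model-implied
pooled 4×4 covariance of (age, education, DSR, MMSE) — between-group
means plus within-group covariances, with each non-linear marginal's
first Hermite coefficient and actual SD computed by quadrature to
account for copula attenuation (the zero-inflated AD marginal and the
MMSE ceiling at 30 both attenuate) — and root-finds the loading.
Empirically the generated cohorts reproduce the target to within
sampling error.  The retest score (a configurable fraction of one
group, default 56/134 of MCI) uses an observed-scale linear blend at
the target test–retest correlation (default 0.887).

**Randomness.**  One root seed; each group consumes its own child
stream (`SeedSequence.spawn`), so appending a group never perturbs
existing groups' draws (the MMSE column alone changes if the group mix
changes, because the coupling is recalibrated).

**What the generator does not emulate** — and what passing tests
therefore do not show about real data: item-level response patterns,
age–education covariance, non-normal demographic shapes, diagnostic
misclassification, dropout, practice effects at retest beyond a fixed
correlation, and any real-data irregularity of the score distributions
beyond first and second moments plus a floor mass.  In particular,
published *stratified* sensitivities/specificities at specific printed
cutoffs depend on distributional detail that two moments cannot carry;
the simulation reproduces AUCs and the broad cutoff locations, not
cell-level operating points.

## Norms and Petersen cutoffs

Normative cells are tabulated per age band (default 50–64, 65–74,
75–85) × education stratum (≤ 9 vs > 9 years, plus pooled), for ISR and
DSR: n, mean, sample SD (n−1), 5th and 10th percentiles, retention.
Percentiles use the weighted-average estimator at position (n+1)p —
the convention of the legacy statistical software used for this class
of study, recognisable by fractional small-sample values such as 3.75;
any numpy quantile method is selectable.  Cohort retention defaults to
the mean of per-subject DSR/ISR ratios (subjects with ISR = 0 are
skipped as undefined); ratio-of-means is available.  The published
retention figures are not the ratio of the printed means, which is what
motivated mean-of-ratios as the default; the aggregation was not stated
and is inferred.  The Petersen convention places the impairment cutoff
at mean − 1.5 SD; the raw value is reported and rounded only for
display (the computed value is reported even where a published rounding
disagrees in the last digit).

## Regression-based T scores

OLS of DSR on education years and age in the normative group
(statsmodels).  The residual SD defaults to the n−1 sample SD of the
residuals — the literal "residual standard deviation" of the original
five-step procedure — rather than the n−p−1 regression RMSE, which is
selectable.  T = 10·(raw − expected)/SD_resid + 50; by construction the
fitting sample has T mean exactly 50 (residuals sum to zero) and SD
exactly 10 under the n−1 convention.  T scores are not clipped.  A
residual SD at or below 1e-8 marks a degenerate (exact-fit) norm and T
scores are refused.

## ROC analysis

Orientation is lower-score-is-positive; a subject screens positive when
the score is strictly below the threshold.  Candidate thresholds are
midpoints between adjacent distinct scores plus sentinels, so integer
data yield half-integer cutoffs and < vs ≤ cannot matter.  The AUC uses
the Mann–Whitney identity P(case < control) + ½ P(tie), computed by
ranks; it equals the trapezoidal area under the swept curve exactly
(both are computed and cross-checked in tests).  The 95% CI uses the
Hanley–McNeil variance (the era's software convention; the method was
not stated in the source), clipped to [0, 1]; a bootstrap CI is
optional.  "Optimal" is the maximum Youden index J = sens + spec − 1;
ties break toward higher sensitivity (screening favours detection),
then the lower threshold.  A closest-to-(0,1) criterion is selectable.
Stratified tables emit one row per stratum × contrast and flag strata
missing a class rather than failing.

## Predictive values

PPV = sens·p/(sens·p + (1−spec)(1−p)) and
NPV = spec·(1−p)/(spec·(1−p) + (1−sens)·p) at base rate p ∈ (0, 1);
reporting rounds to 2 decimals, raw fractions are carried alongside.
The published grid contains a handful of cells inconsistent with its
own sens/spec inputs (transcription slips); tests pin only
arithmetically verified cells, since the formula, not the typo, is
normative.

## Reliability

Test–retest is Pearson r over complete cases (subjects with a retest
value).  Partial correlation residualises both variables on the
covariates plus intercept and correlates the residuals; p-values come
from the t transform with n − 2 − k df.  The p-value printed in the
source for its retest correlation (p = 0.011 at r = 0.887, n = 56) is
internally inconsistent (that r at that n implies a vastly smaller p);
the package reports its own p and does not reproduce the printed one.

## Pipeline determinism

`run_pipeline` writes cohort, classification, norms, norming model,
scored cohort, ROC curves and summary, stratified cutoffs, predictive
grid, reliability summary, a markdown report and a manifest (seed,
source, software version, output list).  No timestamps are embedded, so
a rerun with the same seed is byte-identical.  Any stage failure
removes the files already written in that run and re-raises naming the
stage.  Report tables round as published material does (sens/spec 3 dp,
PPV/NPV 2 dp, norms 2 dp); the CSVs alongside keep raw precision.

## Problem sizes and numerical choices

- Replication runs use the published group sizes (249/134/97; 14 + 50
  for the small dementia groups): 200 replicate cohorts for the
  norming-coefficient recovery and 50 for the discrimination AUC —
  enough to pin the replicate means to ~0.01 (coefficient) and ~0.002
  (AUC) Monte-Carlo standard error.
- `solve_truncnorm` solves on (μ, log σ) with tight least-squares
  tolerances and verifies the achieved moments to 1e-6; solutions and
  marginal objects are memoized.
- Quadrature for the coupling calibration uses a 4001-point grid on
  z ∈ [−8, 8].
- Degenerate inputs: empty norm cells are emitted with n = 0; n = 1
  cells carry no SD and a flag; a fully degenerate generator spec
  (zero residual and demographic SDs) produces a constant score with no
  copula signal rather than NaNs.

## Known limitations

- The classification module cannot reproduce imaging- or
  judgment-based criteria; agreement between simulated group labels and
  operational classification is high but deliberately imperfect
  (MMSE sampling noise around the education minima, as in real intake).
- Stratified cutoff tables on simulated data reproduce structure, not
  the published cell values (see generator limitations above).
- Adjusted-score (T) cutoffs derived from the original cohort are
  treated as reference points only; they depend on that cohort's
  residual distribution and cannot be re-derived from moments.
- PPV/NPV carry no confidence intervals (none were published; none are
  computed).
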