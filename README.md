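# normscreen

Validation analytics for story-recall cognitive screening tests.

Verbal episodic memory declines early on the path from normal aging
through amnestic mild cognitive impairment (MCI) to Alzheimer's disease
(AD), and delayed story recall is one of the most discriminating bedside
measures of it.  A recall test presents a 28-idea story; each idea is
credited 2 (accurate), 1 (partial) or 0 points at an immediate (ISR) and
a delayed (DSR) administration, so totals lie on a 0–56 scale.
`normscreen` implements the full validation workflow such a test goes
through before clinical use, for researchers who need to derive — or
audit — norms and cutoffs from cohort data:

- **Scoring** — idea-unit credits to totals, retention percentage
  (100 × DSR/ISR).
- **Operational classification** — scale-based diagnostic gates
  (education-adjusted MMSE minima, CDR, ADL < 16, HAMD₁₇ ≤ 12, HIS ≤ 4)
  mapping records to NC / MCI / AD-candidate / excluded.
- **Synthetic cohorts** — groups drawn from moment-matched truncated
  normals on the bounded score scale (with a zero-inflated floor mixture
  where a truncated normal cannot attain the target moments), a known
  linear demographic model for the control group, and a Gaussian-copula
  dependence structure calibrated to a target MMSE–DSR partial
  correlation.
- **Stratified norms** — per age-band × education stratum: n, mean, SD,
  5th/10th percentiles (weighted average at position (n+1)p), retention,
  and Petersen cutoffs (mean − 1.5 SD).
- **Regression-based T scores** — OLS of DSR on education and age in the
  normative group; T = 10·(raw − expected)/SD_resid + 50.
- **ROC analysis** — Mann–Whitney AUC (ties get half credit),
  Hanley–McNeil 95% CI, Youden-optimal half-integer cutoffs, stratified
  cutoff tables.
- **Predictive values** — Bayes PPV/NPV at arbitrary base rates,
  published-style grids, sample prevalences.
- **Reliability** — test–retest Pearson r on complete cases; partial
  correlation by residualisation.

## Worked example

```python
from normscreen import (build_roc, generate_cohort, optimal_cutoff,
                        predictive, table1_spec)

cohort = generate_cohort(table1_spec(), seed=42)   # 544 subjects, 5 groups
df = cohort.to_frame()
sub = df[df.group.isin(["MCI", "NC"])]
curve = build_roc(sub.dsr.to_numpy(), (sub.group == "MCI").to_numpy())
best = optimal_cutoff(curve)
print(f"AUC {curve.auc:.3f}; cutoff {best.cutoff:g}, "
      f"sens {best.sens:.3f}, spec {best.spec:.3f}")
pv = predictive(best.sens, best.spec, 0.10)
print(f"at 10% prevalence: PPV {pv.ppv:.2f}, NPV {pv.npv:.2f}")
```

prints

```
AUC 0.895; cutoff 16.5, sens 0.799, spec 0.884
at 10% prevalence: PPV 0.43, NPV 0.98
```

The AUC says a randomly chosen MCI subject scores below a randomly
chosen control about 90% of the time; the Youden-optimal cutoff (a
half-integer, so < versus ≤ is immaterial on integer scores) trades
sensitivity against specificity; and the predictive values translate
that operating point into post-test probabilities at an assumed
population base rate — high NPV (rule-out value) and modest PPV at low
prevalence, the signature of a screening rather than diagnostic test.

The `examples/` directory walks through each capability (simulation,
norms and Petersen cutoffs, T-score norming, ROC cutoffs, predictive
values, and the end-to-end report pipeline); each script prints the
numbers it computes with a note on what they mean.  A thin CLI mirrors
the library (`normscreen simulate|classify|norms|tscore|roc|pv|
reliability|report`).

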