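"""Regression-based demographic norming: raw scores to T scores.

Fits the norming regression (delayed recall on education and age) in
the control group, then converts raw scores to T scores with mean 50
and SD 10 in the norming sample.  A T around 36.5 (about -1.35 residual
SD) corresponds to the screening threshold reported for this test.
"""

from normscreen import (expected_score, fit_norm_regression, generate_cohort,
                        score_cohort, t_score, table1_spec)

cohort = generate_cohort(table1_spec(), seed=42)
norm = fit_norm_regression(cohort.group("NC"))
print(f"expected DSR = {norm.intercept:.3f} + {norm.beta_edu:.3f} x edu "
      f"{norm.beta_age:+.3f} x age   (R^2 = {norm.r_squared:.3f}, "
      f"residual SD = {norm.residual_sd:.2f}, n = {norm.n_fit})")

for age, edu, raw in [(65, 12, 27), (65, 12, 15), (78, 6, 15)]:
    exp = expected_score(norm, age, edu)
    t = t_score(raw, norm, age, edu)
    print(f"age {age}, education {edu}y, raw {raw}: "
          f"expected {exp:.1f}, T = {t:.1f}")
# The same raw score of 15 is much less alarming for a 78-year-old with
# 6 years of schooling than for a well-educated 65-year-old - exactly
# the demographic confound the T transformation removes.

scored = cohort.group("NC")
df = score_cohort(scored, norm)
print(f"norming sample T: mean {df.t.mean():.1f}, SD {df.t.std(ddof=1):.1f}")
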