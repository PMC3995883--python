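"""Test-retest reliability and partial correlation analyses.

Retest reliability is the Pearson correlation between baseline and
retest totals over the complete cases (subjects with a retest score).
The partial correlation between two measures controlling for covariates
is the Pearson correlation of their least-squares residuals after
projecting each on the covariates plus an intercept; p-values come from
the t transform with n - 2 - k degrees of freedom (k covariates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import CohortTable
from .errors import UndefinedValueError, ValidationError


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    controlled_for: tuple = ()


def pearson(x, y) -> CorrelationResult:
    """Plain product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have the same length")
    n = len(x)
    if n < 3:
        raise ValidationError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedValueError("correlation undefined for a constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), n, float(res.pvalue))


def partial_corr(x, y, covariates=None) -> CorrelationResult:
    """Partial correlation of x and y given covariates (residual method).

    ``covariates`` is an (n, k) array (or sequence of k length-n
    vectors); an empty covariate set reduces exactly to :func:`pearson`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        elif cov.shape[0] != len(x) and cov.shape[1] == len(x):
            cov = cov.T
    k = cov.shape[1]
    if k == 0:
        return pearson(x, y)
    n = len(x)
    if x.shape != y.shape or cov.shape[0] != n:
        raise ValidationError("x, y and covariates must align")
    if n <= k + 2:
        raise ValidationError(f"need n > {k + 2} pairs for {k} covariates")
    design = np.column_stack([np.ones(n), cov])
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise UndefinedValueError(
            "partial correlation undefined: zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clip = min(max(r, -0.999999999999), 0.999999999999)
    t = r_clip * np.sqrt(df / (1.0 - r_clip ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r, n, p, tuple(f"cov{i}" for i in range(k)))


def retest_reliability(cohort: CohortTable,
                       group: Optional[str] = None) -> CorrelationResult:
    """Pearson r between baseline DSR and the retest DSR over complete
    cases (subjects with a retest score), optionally within one group."""
    recs = [r for r in cohort
            if r.dsr_retest is not None and (group is None or r.group == group)]
    if len(recs) < 3:
        raise ValidationError(
            f"need at least 3 retested subjects, found {len(recs)}")
    base = [r.dsr for r in recs]
    retest = [r.dsr_retest for r in recs]
    return pearson(base, retest)


def mmse_dsr_partial(cohort: CohortTable,
                     groups: Sequence[str] = ("NC", "MCI", "AD")) -> CorrelationResult:
    """Partial correlation between MMSE and DSR controlling for age and
    education, over the given diagnostic groups."""
    recs = [r for r in cohort if r.group in set(groups)]
    if len(recs) < 5:
        raise ValidationError("too few records for a partial correlation")
    mmse = [r.mmse for r in recs]
    dsr = [r.dsr for r in recs]
    cov = np.column_stack([[r.age for r in recs],
                           [r.education_years for r in recs]])
    out = partial_corr(mmse, dsr, cov)
    return CorrelationResult(out.r, out.n, out.p_value,
                             ("age", "education_years"))
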