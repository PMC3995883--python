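"""Regression-based demographic norming of delayed recall (T scores).

The norming model is an ordinary least squares fit of the delayed
story-recall total on years of education and age in the cognitively
normal group.  A subject's expected score is the model prediction for
their demographics; the residual (raw minus expected) is standardised by
the residual SD to a Z value and rescaled to the T metric,
T = 10 Z + 50, so the fitting sample has T mean 50 and SD 10.

The residual SD defaults to the n-1 sample SD of the fitted residuals
(the convention of the source procedure's "residual Std.Deviation");
the root-mean-square error with n-p-1 degrees of freedom is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable
from .errors import DegenerateNormError, SingularFitError, ValidationError

#: Residual SDs at or below this are treated as a degenerate (exact) fit.
DEGENERATE_SD = 1e-8


@dataclass
class RegressionNorm:
    """Fitted norming model: score = intercept + beta_edu*edu + beta_age*age."""

    intercept: float
    beta_edu: float
    beta_age: float
    residual_sd: float
    n_fit: int
    r_squared: float
    se_beta_edu: float = float("nan")
    se_beta_age: float = float("nan")

    @property
    def degenerate(self) -> bool:
        return self.residual_sd <= DEGENERATE_SD


def _extract(data):
    if isinstance(data, CohortTable):
        df = data.to_frame()
    elif isinstance(data, pd.DataFrame):
        df = data
    else:
        raise ValidationError("expected a CohortTable or DataFrame")
    return (df["dsr"].to_numpy(float), df["education_years"].to_numpy(float),
            df["age"].to_numpy(float))


def fit_norm_regression(data, residual_sd_method: str = "sample") -> RegressionNorm:
    """OLS of DSR on education years and age.

    ``data`` is a :class:`CohortTable` or a frame with ``dsr``,
    ``education_years`` and ``age`` columns; callers are expected to
    pass the normative (cognitively normal) subset.  ``residual_sd_method``
    is ``"sample"`` (n-1 SD of residuals, default) or ``"rmse"``
    (n-p-1 regression root mean squared error).
    """
    y, edu, age = _extract(data)
    n = len(y)
    if n < 4:
        raise ValidationError(f"need at least 4 observations, got {n}")
    X = sm.add_constant(np.column_stack([edu, age]))
    if np.linalg.matrix_rank(X) < 3:
        raise SingularFitError("education and age are constant or collinear")
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    if residual_sd_method == "sample":
        residual_sd = float(np.std(resid, ddof=1))
    elif residual_sd_method == "rmse":
        residual_sd = float(np.sqrt(fit.mse_resid))
    else:
        raise ValidationError(f"unknown residual_sd_method {residual_sd_method!r}")
    return RegressionNorm(
        intercept=float(fit.params[0]),
        beta_edu=float(fit.params[1]),
        beta_age=float(fit.params[2]),
        residual_sd=residual_sd,
        n_fit=n,
        r_squared=float(fit.rsquared),
        se_beta_edu=float(fit.bse[1]),
        se_beta_age=float(fit.bse[2]),
    )


def expected_score(norm: RegressionNorm, age, education_years):
    """Model-expected score for the given demographics (vectorised)."""
    age = np.asarray(age, dtype=float)
    edu = np.asarray(education_years, dtype=float)
    out = norm.intercept + norm.beta_edu * edu + norm.beta_age * age
    return float(out) if out.ndim == 0 else out


def t_score(raw, norm: RegressionNorm, age, education_years):
    """Demographically adjusted T score (mean 50, SD 10 in the norming
    sample).  T is not clipped; values outside [0, 100] are legal."""
    if norm.degenerate:
        raise DegenerateNormError(
            "residual SD is (near) zero; T scores are undefined")
    raw = np.asarray(raw, dtype=float)
    z = (raw - expected_score(norm, age, education_years)) / norm.residual_sd
    t = 10.0 * z + 50.0
    return float(t) if t.ndim == 0 else t


def score_cohort(table: CohortTable, norm: RegressionNorm) -> pd.DataFrame:
    """Cohort frame with ``expected``, ``z`` and ``t`` columns appended."""
    if norm.degenerate:
        raise DegenerateNormError(
            "residual SD is (near) zero; T scores are undefined")
    df = table.to_frame()
    exp = expected_score(norm, df["age"], df["education_years"])
    df["expected"] = exp
    df["z"] = (df["dsr"] - exp) / norm.residual_sd
    df["t"] = 10.0 * df["z"] + 50.0
    return df
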