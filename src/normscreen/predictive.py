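"""Base-rate-adjusted predictive values (Bayes' rule on a 2x2 table).

Sensitivity and specificity are properties of the test, but what a
positive or negative screen means for one patient depends on the
population base rate p:

    PPV = sens*p / (sens*p + (1-spec)*(1-p))
    NPV = spec*(1-p) / (spec*(1-p) + (1-sens)*p)

Reporting rounds to 2 decimals (the convention of published predictive
value grids); raw fractions are always carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import pandas as pd

from .errors import UndefinedValueError, ValidationError


@dataclass(frozen=True)
class PredictiveValues:
    sens: float
    spec: float
    base_rate: float
    ppv: float
    npv: float

    def rounded(self, ndigits: int = 2) -> Tuple[float, float]:
        return round(self.ppv, ndigits), round(self.npv, ndigits)

    def __str__(self):
        return f"{self.ppv:.2f}/{self.npv:.2f}"


def _check_fraction(name: str, value: float, open_interval: bool = False):
    lo_ok = value > 0 if open_interval else value >= 0
    hi_ok = value < 1 if open_interval else value <= 1
    if not (lo_ok and hi_ok):
        kind = "(0, 1)" if open_interval else "[0, 1]"
        raise ValidationError(f"{name}={value} outside {kind}")


def predictive(sens: float, spec: float, base_rate: float) -> PredictiveValues:
    """Positive and negative predictive values at the given base rate."""
    _check_fraction("sens", sens)
    _check_fraction("spec", spec)
    _check_fraction("base_rate", base_rate, open_interval=True)
    p = base_rate
    pos = sens * p + (1.0 - spec) * (1.0 - p)
    neg = spec * (1.0 - p) + (1.0 - sens) * p
    if pos == 0:
        raise UndefinedValueError(
            "PPV undefined: the test is never positive at this base rate")
    if neg == 0:
        raise UndefinedValueError(
            "NPV undefined: the test is never negative at this base rate")
    return PredictiveValues(sens, spec, p, sens * p / pos,
                            spec * (1.0 - p) / neg)


def pv_grid(sens_spec_rows: Iterable, base_rates: Sequence[float],
            formatted: bool = True) -> pd.DataFrame:
    """Predictive-value grid: one row per (cutoff, sens, spec) triple and
    one column per base rate.

    With ``formatted=True`` cells are "ppv/npv" strings at 2 decimals
    (mirroring the published layout); otherwise cells hold (ppv, npv)
    tuples of raw fractions.
    """
    rows = []
    for cutoff, sens, spec in sens_spec_rows:
        row = {"cutoff": cutoff, "sens": sens, "spec": spec}
        for p in base_rates:
            pv = predictive(sens, spec, p)
            key = f"{p:.0%}"
            row[key] = str(pv) if formatted else (pv.ppv, pv.npv)
        rows.append(row)
    return pd.DataFrame(rows)


def sample_prevalence(n_cases: int, n_screened: int) -> float:
    """Observed prevalence as a percentage (one decimal)."""
    if n_screened <= 0 or n_cases < 0 or n_cases > n_screened:
        raise ValidationError("need 0 <= n_cases <= n_screened, n_screened > 0")
    return round(100.0 * n_cases / n_screened, 1)
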