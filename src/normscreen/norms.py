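"""Stratified normative tables and Petersen-style impairment cutoffs.

Norms for the story-recall totals are tabulated in age bands (default
50-64, 65-74, 75-85) split by education (<= 9 vs > 9 years), reporting
per-cell n, mean, sample SD, 5th/10th percentiles and cohort retention.
Percentiles default to the weighted-average estimator at position
(n+1)p — the convention of the legacy SPSS software used for this class
of study, which yields fractional values such as 3.75 on small cells.

The Petersen impairment convention defines a cutoff at the normative
mean minus 1.5 SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import ValidationError
from .scoring import cohort_retention

#: Default age bands covering the 50-85 study range.
DEFAULT_AGE_BANDS = ((50, 64), (65, 74), (75, 85))
#: Default education split in years.
DEFAULT_EDU_SPLIT = 9

EDU_RULES = ("all", "<=split", ">split")


@dataclass(frozen=True)
class Band:
    """One age-by-education stratum; ``edu_rule`` is 'all', '<=split' or
    '>split' with the split in years."""

    age_lo: int
    age_hi: int
    edu_rule: str = "all"
    edu_split: int = DEFAULT_EDU_SPLIT

    def __post_init__(self):
        if self.age_lo > self.age_hi:
            raise ValidationError("age_lo > age_hi")
        if self.edu_rule not in EDU_RULES:
            raise ValidationError(f"edu_rule must be one of {EDU_RULES}")

    def contains(self, age: float, edu: float) -> bool:
        if not (self.age_lo <= age <= self.age_hi):
            return False
        if self.edu_rule == "<=split":
            return edu <= self.edu_split
        if self.edu_rule == ">split":
            return edu > self.edu_split
        return True

    def label(self) -> str:
        age = f"{self.age_lo}-{self.age_hi}"
        if self.edu_rule == "<=split":
            return f"{age}/edu<={self.edu_split}"
        if self.edu_rule == ">split":
            return f"{age}/edu>{self.edu_split}"
        return f"{age}/all"


def default_bands(age_bands=DEFAULT_AGE_BANDS,
                  edu_split: int = DEFAULT_EDU_SPLIT) -> list:
    """The study layout: per age band, an education-low, education-high
    and pooled stratum."""
    bands = []
    for lo, hi in age_bands:
        for rule in ("<=split", ">split", "all"):
            bands.append(Band(lo, hi, rule, edu_split))
    return bands


@dataclass
class NormCell:
    """Normative statistics for one stratum and one measure."""

    band: Band
    measure: str                 # "ISR" or "DSR"
    n: int
    mean: Optional[float]
    sd: Optional[float]
    p5: Optional[float]
    p10: Optional[float]
    retention_pct: Optional[float]
    flags: tuple = ()


def percentile(values, p: float, method: str = "weibull") -> float:
    """Percentile of ``values`` at ``p`` (in percent, 0-100).

    ``method='weibull'`` is the weighted average at position (n+1)p;
    any estimator name accepted by :func:`numpy.quantile` may be given.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot take a percentile of an empty sample")
    return float(np.quantile(values, p / 100.0, method=method))


def build_norm_table(cohort: CohortTable, bands: Optional[Iterable] = None,
                     group: Optional[str] = "NC",
                     percentile_method: str = "weibull",
                     retention_method: str = "mean_of_ratios") -> list:
    """Per-stratum normative cells for ISR and DSR.

    ``group`` restricts the cohort (default the normal-cognition group;
    pass ``None`` to use all records).  Empty cells are emitted with
    n = 0 and absent statistics; single-subject cells report a mean but
    no SD and are flagged.
    """
    if bands is None:
        bands = default_bands()
    if group is not None:
        cohort = cohort.group(group)
    age = np.array([r.age for r in cohort])
    edu = np.array([r.education_years for r in cohort])
    isr = np.array([r.isr for r in cohort], dtype=float)
    dsr = np.array([r.dsr for r in cohort], dtype=float)

    cells = []
    for band in bands:
        if len(cohort):
            mask = np.array([band.contains(a, e) for a, e in zip(age, edu)])
        else:
            mask = np.zeros(0, dtype=bool)
        n = int(mask.sum())
        for measure, scores in (("ISR", isr), ("DSR", dsr)):
            if n == 0:
                cells.append(NormCell(band, measure, 0, None, None, None,
                                      None, None, ("empty",)))
                continue
            x = scores[mask]
            flags = ()
            mean = float(np.mean(x))
            if n == 1:
                sd = None
                flags = ("n=1: SD undefined",)
            else:
                sd = float(np.std(x, ddof=1))
            retention = None
            if (isr[mask] > 0).any():
                retention = cohort_retention(dsr[mask], isr[mask],
                                             method=retention_method)
            cells.append(NormCell(
                band, measure, n, mean, sd,
                percentile(x, 5, percentile_method),
                percentile(x, 10, percentile_method),
                retention, flags))
    return cells


def petersen_cutoff(mean: float, sd: float) -> float:
    """Impairment cutoff at the normative mean minus 1.5 SD (raw value;
    round to one decimal for reporting)."""
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    return mean - 1.5 * sd


def norms_frame(cells: Iterable) -> pd.DataFrame:
    """Flatten norm cells into a tidy frame (one row per cell), with the
    Petersen cutoff alongside."""
    rows = []
    for c in cells:
        cut = petersen_cutoff(c.mean, c.sd) if (c.mean is not None
                                                and c.sd is not None) else None
        rows.append({
            "stratum": c.band.label(), "measure": c.measure, "n": c.n,
            "mean": c.mean, "sd": c.sd, "p5": c.p5, "p10": c.p10,
            "retention_pct": c.retention_pct,
            "petersen_cutoff": cut,
            "flags": ";".join(c.flags),
        })
    return pd.DataFrame(rows)
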