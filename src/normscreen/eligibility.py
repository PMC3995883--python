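"""Operational diagnostic classification from tabular scale scores.

Maps a subject record to NC / MCI / AD_candidate / excluded using the
scale-based gates only: education-adjusted MMSE minima, global and
memory-domain CDR, functional independence (ADL < 16), a depression gate
(17-item HAMD <= 12) and a vascular gate (HIS <= 4).  Imaging and
clinician-judgment criteria cannot be operationalised from a table, so
the dementia-track output is labelled ``AD_candidate`` rather than AD.

Gate evaluation order for the excluded reason (the source criteria give
no order, so one is fixed here): depression gate, then vascular gate,
then the cognitive/functional gates of the track selected by CDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .cohort import CohortTable, SubjectRecord
from .errors import ClassificationError

#: Exclusive MMSE minima by education level: a subject is cognitively
#: "in the normal range" only if MMSE is strictly above the level's value.
MMSE_MINIMUMS = {"higher": 26, "middle": 23, "primary": 22, "illiterate": 19}

#: ADL threshold: scores below this mean fully independent daily living.
ADL_INDEPENDENT_BELOW = 16
#: Depression gate on the 17-item HAMD (inclusive maximum).
HAMD_MAX = 12
#: Vascular gate on the Hachinski Ischemia Scale (inclusive maximum).
HIS_MAX = 4

LABELS = ("NC", "MCI", "AD_candidate", "excluded")


def mmse_min(education_level: str) -> int:
    """Exclusive lower MMSE bound for the given education level."""
    try:
        return MMSE_MINIMUMS[education_level]
    except KeyError:
        raise ClassificationError(
            f"unknown education level {education_level!r}; "
            f"expected one of {sorted(MMSE_MINIMUMS)}") from None


@dataclass(frozen=True)
class Classification:
    label: str            # one of LABELS
    reason: Optional[str] = None   # first failing gate when excluded

    def __str__(self):
        if self.label == "excluded":
            return f"excluded({self.reason})"
        return self.label


_MANDATORY = ("mmse", "adl", "cdr_global", "cdr_memory", "his", "hamd17",
              "education_level")


def classify(record: SubjectRecord) -> Classification:
    """Apply the operational screening rules to one record.

    Exactly one label is returned.  NC requires CDR 0, education-normal
    MMSE and independent ADL; MCI requires CDR 0.5 with memory domain
    0.5, education-normal MMSE, independent ADL and clean depression and
    vascular gates; the AD candidate track requires below-normal MMSE,
    CDR >= 0.5, impaired ADL and clean depression and vascular gates.
    """
    for name in _MANDATORY:
        if getattr(record, name, None) is None:
            raise ClassificationError(f"mandatory field '{name}' missing "
                                      f"for subject {record.id!r}")
    minimum = mmse_min(record.education_level)
    mmse_normal = record.mmse > minimum
    adl_ok = record.adl < ADL_INDEPENDENT_BELOW
    hamd_ok = record.hamd17 <= HAMD_MAX
    his_ok = record.his <= HIS_MAX

    if record.cdr_global == 0 and mmse_normal and adl_ok:
        return Classification("NC")
    if (record.cdr_global == 0.5 and record.cdr_memory == 0.5
            and mmse_normal and adl_ok and hamd_ok and his_ok):
        return Classification("MCI")
    if (not mmse_normal and record.cdr_global >= 0.5
            and record.adl >= ADL_INDEPENDENT_BELOW and hamd_ok and his_ok):
        return Classification("AD_candidate")

    # Excluded: report the first failing gate in the documented order.
    if not hamd_ok:
        return Classification("excluded", "depression")
    if not his_ok:
        return Classification("excluded", "vascular")
    if record.cdr_global == 0:
        if not mmse_normal:
            return Classification("excluded", "mmse_below_education_minimum")
        return Classification("excluded", "adl_impaired")
    if record.cdr_global == 0.5 and mmse_normal:
        if record.cdr_memory != 0.5:
            return Classification("excluded", "cdr_memory_not_0.5")
        return Classification("excluded", "adl_impaired")
    if mmse_normal:
        # CDR >= 0.5 (dementia-range) but MMSE still in the normal range.
        return Classification("excluded", "mmse_cdr_discordant")
    return Classification("excluded", "adl_preserved_with_low_mmse")


def classify_cohort(table: CohortTable) -> pd.DataFrame:
    """Classify every record; returns id, given group, label and reason."""
    rows = []
    for rec in table:
        c = classify(rec)
        rows.append({"id": rec.id, "group": rec.group,
                     "label": c.label, "reason": c.reason or ""})
    return pd.DataFrame(rows, columns=["id", "group", "label", "reason"])
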