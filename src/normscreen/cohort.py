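"""Subject-level cohort tables: record types, validation, and CSV round-trip.

A cohort is one row per participant with demographics, clinical scale
scores (MMSE, ADL, CDR, HIS, 17-item HAMD), immediate and delayed
story-recall totals (ISR/DSR, each 0-56), an optional 3-month DSR retest,
and a diagnostic group label.  The CSV dialect is comma-separated UTF-8
with a fixed lowercase header; missing optional values are empty strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import pandas as pd

from .errors import FormatError, RowParseError, ValidationError

#: Canonical column order for cohort CSV files.
COLUMNS = [
    "id", "age", "education_years", "education_level", "sex", "group",
    "mmse", "adl", "cdr_global", "cdr_memory", "his", "hamd17",
    "isr", "dsr", "dsr_retest",
]

SEXES = {"male", "female"}
GROUPS = {"NC", "MCI", "AD", "VaD", "other_dementia", "depression", "VCI",
          "unclassified"}
EDUCATION_LEVELS = {"illiterate", "primary", "middle", "higher"}
CDR_LEVELS = {0.0, 0.5, 1.0, 2.0, 3.0}

#: Maximum story-recall total: 28 ideas x 2 points.
MAX_RECALL = 56


@dataclass
class SubjectRecord:
    """One participant.

    ``age`` and ``education_years`` are in years; ``isr``/``dsr`` are
    story-recall totals on the 0-56 scale; ``adl`` is scored so that
    higher means more impaired (independent living is ADL < 16).
    """

    id: str
    age: float
    education_years: float
    education_level: str
    sex: str
    group: str
    mmse: int
    adl: int
    cdr_global: float
    cdr_memory: float
    his: int
    hamd17: int
    isr: int
    dsr: int
    dsr_retest: Optional[int] = None

    def hard_violations(self) -> list[str]:
        """Invariant violations that strict reading refuses to accept."""
        out = []
        if not (0 <= self.isr <= MAX_RECALL):
            out.append(f"isr={self.isr} outside 0-{MAX_RECALL}")
        if not (0 <= self.dsr <= MAX_RECALL):
            out.append(f"dsr={self.dsr} outside 0-{MAX_RECALL}")
        if self.dsr_retest is not None and not (0 <= self.dsr_retest <= MAX_RECALL):
            out.append(f"dsr_retest={self.dsr_retest} outside 0-{MAX_RECALL}")
        if not (0 <= self.mmse <= 30):
            out.append(f"mmse={self.mmse} outside 0-30")
        if self.sex not in SEXES:
            out.append(f"sex={self.sex!r} not in {sorted(SEXES)}")
        if self.group not in GROUPS:
            out.append(f"group={self.group!r} not recognised")
        if self.education_level not in EDUCATION_LEVELS:
            out.append(f"education_level={self.education_level!r} not recognised")
        if float(self.cdr_global) not in CDR_LEVELS:
            out.append(f"cdr_global={self.cdr_global} not a CDR level")
        if float(self.cdr_memory) not in CDR_LEVELS:
            out.append(f"cdr_memory={self.cdr_memory} not a CDR level")
        if self.his < 0:
            out.append(f"his={self.his} negative")
        if self.hamd17 < 0:
            out.append(f"hamd17={self.hamd17} negative")
        if self.education_years < 0:
            out.append("education_years negative")
        return out

    def soft_flags(self) -> list[str]:
        """Deviations that are flagged but never rejected (study-age range)."""
        out = []
        if not (50 <= self.age <= 85):
            out.append(f"age={self.age:g} outside study range 50-85")
        return out


@dataclass
class CohortTable:
    """Ordered collection of :class:`SubjectRecord` with provenance.

    ``provenance`` is either ``read_from_file:<path>`` or
    ``simulated(seed=<seed>)``.  ``flags`` collects soft (and, in lenient
    reads, hard) violations keyed by subject id.
    """

    records: list[SubjectRecord]
    provenance: str = "unspecified"
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate) -> "CohortTable":
        kept = [r for r in self.records if predicate(r)]
        return CohortTable(kept, provenance=self.provenance)

    def group(self, *labels: str) -> "CohortTable":
        wanted = set(labels)
        return self.subset(lambda r: r.group in wanted)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({f.name: getattr(r, f.name) for f in fields(SubjectRecord)})
        df = pd.DataFrame(rows, columns=COLUMNS)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "unspecified",
                   strict: bool = True) -> "CohortTable":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {missing}")
        records, flags = [], {}
        for i, row in enumerate(df.itertuples(index=False), start=1):
            rec = _parse_row(row._asdict(), i)
            hard = rec.hard_violations()
            soft = rec.soft_flags()
            if hard and strict:
                raise RowParseError(i, "; ".join(hard))
            if hard or soft:
                flags[rec.id] = hard + soft
            records.append(rec)
        return cls(records, provenance=provenance, flags=flags)


def _num(value, caster, name: str, optional: bool = False):
    if value is None or (isinstance(value, str) and value.strip() == ""):
        if optional:
            return None
        raise ValueError(f"mandatory field '{name}' is empty")
    if isinstance(value, float) and pd.isna(value):
        if optional:
            return None
        raise ValueError(f"mandatory field '{name}' is empty")
    try:
        return caster(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"cannot parse {name}={value!r}") from exc


def _int(value):
    f = float(value)
    if f != int(f):
        raise ValueError(f"{value!r} is not an integer")
    return int(f)


def _parse_row(d: dict, rownum: int) -> SubjectRecord:
    try:
        return SubjectRecord(
            id=str(d["id"]),
            age=_num(d["age"], float, "age"),
            education_years=_num(d["education_years"], float, "education_years"),
            education_level=str(d["education_level"]).strip(),
            sex=str(d["sex"]).strip(),
            group=str(d["group"]).strip(),
            mmse=_num(d["mmse"], _int, "mmse"),
            adl=_num(d["adl"], _int, "adl"),
            cdr_global=_num(d["cdr_global"], float, "cdr_global"),
            cdr_memory=_num(d["cdr_memory"], float, "cdr_memory"),
            his=_num(d["his"], _int, "his"),
            hamd17=_num(d["hamd17"], _int, "hamd17"),
            isr=_num(d["isr"], _int, "isr"),
            dsr=_num(d["dsr"], _int, "dsr"),
            dsr_retest=_num(d["dsr_retest"], _int, "dsr_retest", optional=True),
        )
    except ValueError as exc:
        raise RowParseError(rownum, str(exc)) from exc


def read_cohort(path, strict: bool = True) -> CohortTable:
    """Read a cohort CSV.

    In strict mode any hard invariant violation (score out of range,
    unknown category) raises; in lenient mode violating rows are kept and
    recorded in ``table.flags``.  Out-of-range ages are always flagged,
    never rejected.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot read {path}: {exc}") from exc
    table = CohortTable.from_frame(df, provenance=f"read_from_file:{path}",
                                   strict=strict)
    return table


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    if isinstance(value, float):
        if value == int(value):
            return str(int(value))
        return format(value, ".10g")
    return str(value)


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort CSV such that ``read_cohort`` recovers the table.

    Integer-valued reals are written without a decimal point; optional
    missing values are written as empty strings.
    """
    df = table.to_frame()
    out = df.copy()
    for col in COLUMNS:
        out[col] = [_fmt(v) for v in df[col]]
    out.to_csv(path, index=False, columns=COLUMNS)
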