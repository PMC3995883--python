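"""Story-recall scoring: idea-unit credits, totals, and retention.

The recall story contains 28 idea units.  Each idea is credited 2 points
for accurate recall (or an accurate paraphrase), 1 point for vague or
partial recall, and 0 otherwise, so a recall total lies in 0-56.  The
same scheme is applied at the immediate (ISR) and delayed (DSR) phases;
retention is the delayed/immediate ratio expressed as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import UndefinedValueError, ValidationError

#: Number of idea units in the story.
N_IDEAS = 28
#: Maximum recall total (all ideas fully credited).
MAX_SCORE = 2 * N_IDEAS


@dataclass(frozen=True)
class RecallCredits:
    """Per-idea credits for one administration of the story."""

    credits: tuple
    phase: Literal["immediate", "delayed"] = "immediate"

    def __post_init__(self):
        object.__setattr__(self, "credits", tuple(self.credits))
        if len(self.credits) != N_IDEAS:
            raise ValidationError(
                f"expected {N_IDEAS} idea credits, got {len(self.credits)}")
        bad = [c for c in self.credits if c not in (0, 1, 2)]
        if bad:
            raise ValidationError(f"credits must be 0, 1 or 2; got {bad[:5]}")


def total_score(credits) -> int:
    """Sum of the 28 per-idea credits (0-56).

    Accepts a :class:`RecallCredits` or a plain length-28 sequence of
    credits in {0, 1, 2}.
    """
    if not isinstance(credits, RecallCredits):
        credits = RecallCredits(tuple(credits))
    return int(sum(credits.credits))


def retention_pct(dsr: float, isr: float) -> float:
    """Percentage of the story retained: 100 * DSR / ISR.

    Undefined when ISR = 0 (nothing was registered to retain); raises
    :class:`UndefinedValueError` rather than returning 0 or infinity.
    """
    if isr == 0:
        raise UndefinedValueError("retention undefined: ISR is 0")
    if dsr < 0 or isr < 0:
        raise ValidationError("scores must be non-negative")
    return 100.0 * dsr / isr


def cohort_retention(dsr, isr, method: str = "mean_of_ratios") -> float:
    """Cohort-level retention percentage.

    ``mean_of_ratios`` (default) averages per-subject DSR/ISR ratios,
    skipping subjects with ISR = 0; ``ratio_of_means`` divides the cohort
    mean DSR by the cohort mean ISR.  The two differ whenever retention
    covaries with ISR, which is why both are exposed.
    """
    dsr = np.asarray(dsr, dtype=float)
    isr = np.asarray(isr, dtype=float)
    if dsr.shape != isr.shape:
        raise ValidationError("dsr and isr must have the same length")
    if method == "mean_of_ratios":
        ok = isr > 0
        if not ok.any():
            raise UndefinedValueError("no subject has ISR > 0")
        return float(np.mean(100.0 * dsr[ok] / isr[ok]))
    if method == "ratio_of_means":
        if isr.mean() == 0:
            raise UndefinedValueError("mean ISR is 0")
        return float(100.0 * dsr.mean() / isr.mean())
    raise ValidationError(f"unknown retention method {method!r}")


def read_item_credits(path) -> pd.DataFrame:
    """Read an item-level credits CSV (id, phase, idea_01..idea_28).

    Returns a frame with one row per (id, phase) and a ``total`` column
    computed by :func:`total_score`.
    """
    df = pd.read_csv(path)
    idea_cols = [f"idea_{i:02d}" for i in range(1, N_IDEAS + 1)]
    missing = [c for c in ["id", "phase", *idea_cols] if c not in df.columns]
    if missing:
        raise ValidationError(f"item-level file missing column(s): {missing}")
    totals = [total_score(row) for row in df[idea_cols].to_numpy()]
    return pd.DataFrame({"id": df["id"], "phase": df["phase"], "total": totals})
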