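"""ROC analysis for a lower-is-impaired screening score.

A subject tests positive when their score falls strictly below the
threshold; candidate thresholds are the midpoints between adjacent
distinct observed scores plus sentinels outside the observed range, so
on integer scores every reported cutoff is a half-integer and < versus
<= is immaterial.

The AUC is computed by the Mann-Whitney identity
AUC = P(case < control) + 0.5 P(case = control), which equals the
trapezoidal area under the swept curve exactly.  Its 95% confidence
interval uses the Hanley-McNeil variance formula by default (the
convention of the era's statistical software); a bootstrap interval is
available.  The "optimal" cutoff maximises the Youden index
J = sensitivity + specificity - 1, with ties broken toward higher
sensitivity (screening favours detection) and then the lower threshold;
a closest-to-(0,1) criterion is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import CohortTable
from .errors import RocError, ValidationError


@dataclass
class RocCurve:
    """Threshold sweep with per-threshold sensitivity/specificity."""

    thresholds: np.ndarray      # ascending candidate cutoffs
    sens: np.ndarray            # P(case score < threshold)
    spec: np.ndarray            # P(control score >= threshold)
    auc: float
    auc_se: float
    auc_ci: Tuple[float, float]
    n_cases: int
    n_controls: int
    orientation: str = "lower_is_positive"


@dataclass
class CutoffResult:
    cutoff: float
    sens: float
    spec: float

    @property
    def youden_j(self) -> float:
        return self.sens + self.spec - 1.0


def mann_whitney_auc(cases, controls) -> float:
    """AUC = P(case < control) + 0.5 P(case = control)."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    n1, n2 = len(cases), len(controls)
    ranks = rankdata(np.concatenate([cases, controls]))
    # rank sum of cases counts pairs where case > control (+ half ties)
    u_case_greater = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return 1.0 - u_case_greater / (n1 * n2)


def hanley_mcneil_se(auc: float, n_cases: int, n_controls: int) -> float:
    """Hanley-McNeil standard error of a nonparametric AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc)
           + (n_cases - 1) * (q1 - auc ** 2)
           + (n_controls - 1) * (q2 - auc ** 2)) / (n_cases * n_controls)
    return float(np.sqrt(max(var, 0.0)))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[distinct[0] - 0.5], mids, [distinct[-1] + 0.5]])


def build_roc(scores, case_labels, bootstrap_ci: bool = False,
              n_boot: int = 2000, seed: int = 0) -> RocCurve:
    """ROC curve for ``scores`` with boolean ``case_labels`` (True =
    impaired group; positive test = score strictly below threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(case_labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and case_labels must align")
    cases, controls = scores[labels], scores[~labels]
    if len(cases) == 0 or len(controls) == 0:
        raise RocError("ROC undefined: need at least one case and one control")
    thresholds = _candidate_thresholds(scores)
    sens = np.array([(cases < t).mean() for t in thresholds])
    spec = np.array([(controls >= t).mean() for t in thresholds])
    auc = mann_whitney_auc(cases, controls)
    if bootstrap_ci:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = mann_whitney_auc(
                rng.choice(cases, size=len(cases), replace=True),
                rng.choice(controls, size=len(controls), replace=True))
        lo, hi = np.quantile(boots, [0.025, 0.975])
        se = float(np.std(boots, ddof=1))
    else:
        se = hanley_mcneil_se(auc, len(cases), len(controls))
        lo, hi = auc - 1.96 * se, auc + 1.96 * se
    lo, hi = max(lo, 0.0), min(hi, 1.0)
    return RocCurve(thresholds, sens, spec, float(auc), se,
                    (float(lo), float(hi)), len(cases), len(controls))


def trapezoid_auc(curve: RocCurve) -> float:
    """Area under the (1-specificity, sensitivity) polyline — equal to
    the Mann-Whitney AUC; exposed for cross-checks."""
    fpr = 1.0 - curve.spec
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(curve.sens[order], fpr[order]))


def optimal_cutoff(curve: RocCurve, criterion: str = "youden") -> CutoffResult:
    """Best threshold under ``criterion`` ('youden' or 'closest_topleft').

    Youden ties break toward higher sensitivity, then the lower
    threshold.
    """
    if criterion == "youden":
        objective = curve.sens + curve.spec - 1.0
    elif criterion == "closest_topleft":
        objective = -np.hypot(1.0 - curve.sens, 1.0 - curve.spec)
    else:
        raise ValidationError(f"unknown criterion {criterion!r}")
    best = objective.max()
    tied = np.flatnonzero(np.isclose(objective, best, rtol=0, atol=1e-12))
    best_sens = curve.sens[tied].max()
    tied = tied[np.isclose(curve.sens[tied], best_sens, rtol=0, atol=1e-12)]
    idx = tied[np.argmin(curve.thresholds[tied])]
    return CutoffResult(float(curve.thresholds[idx]),
                        float(curve.sens[idx]), float(curve.spec[idx]))


def stratified_cutoffs(cohort: CohortTable, bands, contrasts,
                       score: str = "dsr",
                       criterion: str = "youden") -> pd.DataFrame:
    """One optimal-cutoff row per (stratum x contrast).

    ``bands`` is an iterable of :class:`normscreen.norms.Band` (include a
    whole-range band for the unstratified row); ``contrasts`` is an
    iterable of (case_group, control_group) label pairs.  Strata missing
    a class are flagged and carry no cutoff.
    """
    df = cohort.to_frame()
    rows = []
    for band in bands:
        in_band = df.apply(
            lambda r: band.contains(r["age"], r["education_years"]), axis=1)
        for case_grp, control_grp in contrasts:
            sub = df[in_band & df["group"].isin([case_grp, control_grp])]
            n_case = int((sub["group"] == case_grp).sum())
            n_control = int((sub["group"] == control_grp).sum())
            row = {"stratum": band.label(),
                   "contrast": f"{case_grp}_vs_{control_grp}",
                   "n_case": n_case, "n_control": n_control}
            if n_case == 0 or n_control == 0:
                row.update({"cutoff": None, "sens": None, "spec": None,
                            "youden_j": None, "auc": None,
                            "flag": "missing_class"})
            else:
                curve = build_roc(sub[score].to_numpy(),
                                  (sub["group"] == case_grp).to_numpy())
                best = optimal_cutoff(curve, criterion)
                row.update({"cutoff": best.cutoff, "sens": best.sens,
                            "spec": best.spec, "youden_j": best.youden_j,
                            "auc": curve.auc, "flag": ""})
            rows.append(row)
    return pd.DataFrame(rows)


def plot_roc(curves: dict, path=None):
    """Plot one or more ROC curves (label -> RocCurve).  Returns the
    matplotlib figure; saves to ``path`` when given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        fpr = 1.0 - curve.spec
        order = np.argsort(fpr, kind="stable")
        ax.plot(fpr[order], curve.sens[order],
                label=f"{label} (AUC {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
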