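"""End-to-end validation pipeline and study-style report bundle.

Sequences the full analysis — acquire cohort (read or simulate),
operational classification, stratified norms, regression-based T
scores, ROC cutoffs per contrast (raw and adjusted scores), predictive
value grid, reliability — and writes every artifact with a manifest of
inputs, seed and software version.  Given a fixed seed the bundle is
byte-identical across reruns (no timestamps are embedded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import read_cohort, write_cohort
from .eligibility import classify_cohort
from .errors import PipelineError, ValidationError
from .norms import Band, build_norm_table, default_bands, norms_frame
from .predictive import pv_grid
from .regression import fit_norm_regression, score_cohort
from .reliability import mmse_dsr_partial, retest_reliability
from .roc import build_roc, optimal_cutoff, stratified_cutoffs
from .simulate import CohortSpec, generate_cohort, load_cohort_spec, table1_spec

log = logging.getLogger("normscreen.pipeline")

DEFAULT_CONTRASTS = (("MCI", "NC"), ("AD", "NC"))
DEFAULT_BASE_RATES = (0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass
class PipelineConfig:
    """Input source plus analysis layout for one pipeline run.

    Exactly one of ``input_path`` (a cohort CSV) or ``spec`` (a
    simulation spec; ``None`` with ``input_path=None`` falls back to the
    packaged default spec) is the cohort source.
    """

    out_dir: Path
    input_path: Optional[Path] = None
    spec: Optional[CohortSpec] = None
    seed: Optional[int] = None
    age_bands: Sequence = ((50, 64), (65, 74), (75, 85))
    edu_split: int = 9
    contrasts: Sequence = DEFAULT_CONTRASTS
    base_rates: Sequence[float] = DEFAULT_BASE_RATES
    norm_group: str = "NC"
    make_plots: bool = False


def load_pipeline_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    spec = None
    if "simulate" in d:
        sim = d["simulate"]
        spec = load_cohort_spec(sim) if isinstance(sim, str) else None
        if spec is None:
            from .simulate import _spec_from_dict
            spec = _spec_from_dict(sim)
    return PipelineConfig(
        out_dir=Path(d["out_dir"]),
        input_path=Path(d["input"]) if "input" in d else None,
        spec=spec,
        seed=d.get("seed"),
        age_bands=tuple(tuple(b) for b in d.get("age_bands",
                                                ((50, 64), (65, 74), (75, 85)))),
        edu_split=d.get("edu_split", 9),
        contrasts=tuple(tuple(c) for c in d.get("contrasts", DEFAULT_CONTRASTS)),
        base_rates=tuple(d.get("base_rates", DEFAULT_BASE_RATES)),
        norm_group=d.get("norm_group", "NC"),
        make_plots=bool(d.get("make_plots", False)),
    )


def _validate_config(config: PipelineConfig):
    if config.input_path is not None and config.spec is not None:
        raise ValidationError("give either input_path or spec, not both")
    known = None
    if config.spec is not None:
        known = {g.label for g in config.spec.groups}
    elif config.input_path is None:
        known = {g.label for g in table1_spec().groups}
    for case, control in config.contrasts:
        if known is not None and (case not in known or control not in known):
            raise ValidationError(
                f"contrast ({case}, {control}) names a group absent from "
                f"the cohort spec {sorted(known)}")
    for lo, hi in config.age_bands:
        Band(lo, hi)  # raises on a malformed band


def _bands_for(config: PipelineConfig, include_overall: bool = True) -> list:
    bands = []
    if include_overall:
        lo = min(b[0] for b in config.age_bands)
        hi = max(b[1] for b in config.age_bands)
        bands.append(Band(lo, hi, "all", config.edu_split))
    for alo, ahi in config.age_bands:
        for rule in ("all", "<=split", ">split"):
            bands.append(Band(alo, ahi, rule, config.edu_split))
    return bands


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the bundle as a dict of in-memory
    results and writes the artifact files under ``config.out_dir``.

    Any stage failure removes files already written in this run and
    re-raises as :class:`PipelineError` naming the stage.
    """
    _validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    bundle: dict = {}
    stage = "setup"
    try:
        stage = "acquire_cohort"
        if config.input_path is not None:
            cohort = read_cohort(config.input_path)
        else:
            spec = config.spec if config.spec is not None else table1_spec()
            cohort = generate_cohort(spec, seed=config.seed)
        log.info("cohort: %d records (%s)", len(cohort), cohort.provenance)
        bundle["cohort"] = cohort
        emit("cohort.csv", lambda p: write_cohort(cohort, p))

        stage = "classify"
        labels = classify_cohort(cohort)
        agreement = pd.crosstab(labels["group"], labels["label"])
        bundle["classification"] = labels
        bundle["classification_agreement"] = agreement
        emit("classification.csv", lambda p: labels.to_csv(p, index=False))

        stage = "norms"
        norm_bands = default_bands(config.age_bands, config.edu_split)
        cells = build_norm_table(cohort, norm_bands, group=config.norm_group)
        norms_df = norms_frame(cells)
        bundle["norms"] = norms_df
        emit("norms.csv", lambda p: norms_df.to_csv(p, index=False))

        stage = "regression_norming"
        norm = fit_norm_regression(cohort.group(config.norm_group))
        scored = score_cohort(cohort, norm)
        bundle["regression_norm"] = norm
        bundle["scored"] = scored
        emit("regression_norm.json", lambda p: p.write_text(json.dumps({
            "intercept": norm.intercept, "beta_edu": norm.beta_edu,
            "beta_age": norm.beta_age, "residual_sd": norm.residual_sd,
            "n_fit": norm.n_fit, "r_squared": norm.r_squared}, indent=2)))
        emit("scored.csv", lambda p: scored.to_csv(p, index=False))

        stage = "roc"
        curves, cut_rows = {}, []
        for case, control in config.contrasts:
            sub = cohort.group(case, control)
            df = sub.to_frame()
            for score_col, tag in (("dsr", "raw"), ("t", "adjusted")):
                values = (df["dsr"].to_numpy() if score_col == "dsr" else
                          scored.loc[scored["group"].isin([case, control]),
                                     "t"].to_numpy())
                curve = build_roc(values, (df["group"] == case).to_numpy())
                best = optimal_cutoff(curve)
                key = f"{case}_vs_{control}_{tag}"
                curves[key] = curve
                cut_rows.append({
                    "contrast": f"{case}_vs_{control}", "score": tag,
                    "auc": curve.auc, "auc_ci_low": curve.auc_ci[0],
                    "auc_ci_high": curve.auc_ci[1], "cutoff": best.cutoff,
                    "sens": best.sens, "spec": best.spec,
                    "youden_j": best.youden_j})
        roc_summary = pd.DataFrame(cut_rows)
        bundle["roc"] = curves
        bundle["roc_summary"] = roc_summary
        emit("roc_summary.csv", lambda p: roc_summary.to_csv(p, index=False))
        emit("roc.json", lambda p: p.write_text(json.dumps({
            k: {"auc": c.auc, "auc_ci": list(c.auc_ci),
                "thresholds": c.thresholds.tolist(),
                "sens": c.sens.tolist(), "spec": c.spec.tolist()}
            for k, c in curves.items()}, indent=2)))
        if config.make_plots:
            from .roc import plot_roc
            emit("roc.png", lambda p: plot_roc(
                {k: v for k, v in curves.items() if k.endswith("raw")}, p))

        stage = "stratified_cutoffs"
        strat = stratified_cutoffs(cohort, _bands_for(config), config.contrasts)
        bundle["stratified_cutoffs"] = strat
        emit("stratified_cutoffs.csv", lambda p: strat.to_csv(p, index=False))

        stage = "predictive_values"
        rows = [(r["cutoff"], r["sens"], r["spec"])
                for _, r in roc_summary[roc_summary["score"] == "raw"].iterrows()]
        grid = pv_grid(rows, config.base_rates)
        grid.insert(0, "contrast",
                    roc_summary.loc[roc_summary["score"] == "raw",
                                    "contrast"].to_numpy())
        bundle["pv_grid"] = grid
        emit("pv_grid.csv", lambda p: grid.to_csv(p, index=False))

        stage = "reliability"
        rel = {}
        try:
            rt = retest_reliability(cohort)
            rel["retest"] = {"r": rt.r, "n": rt.n, "p_value": rt.p_value}
        except ValidationError:
            rel["retest"] = None
        pc = mmse_dsr_partial(cohort)
        rel["mmse_dsr_partial"] = {"r": pc.r, "n": pc.n, "p_value": pc.p_value,
                                   "controlled_for": list(pc.controlled_for)}
        bundle["reliability"] = rel
        emit("reliability.json",
             lambda p: p.write_text(json.dumps(rel, indent=2)))

        stage = "report"
        emit("report.md", lambda p: p.write_text(_render_report(config, bundle)))
        emit("manifest.json", lambda p: p.write_text(json.dumps({
            "software": f"normscreen {__version__}",
            "seed": config.seed,
            "source": (str(config.input_path) if config.input_path
                       else bundle["cohort"].provenance),
            "contrasts": [list(c) for c in config.contrasts],
            "age_bands": [list(b) for b in config.age_bands],
            "edu_split": config.edu_split,
            "base_rates": list(config.base_rates),
            "outputs": [p.name for p in written] + ["manifest.json"],
        }, indent=2)))
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    bundle["outputs"] = written
    return bundle


def _render_report(config: PipelineConfig, bundle: dict) -> str:
    """Markdown summary with study-style rounding (sens/spec 3 dp,
    PPV/NPV 2 dp, norms 2 dp); raw-precision CSVs sit alongside."""
    lines = ["# Story-recall screening validation report", ""]
    cohort = bundle["cohort"]
    lines += [f"Source: {cohort.provenance}; n = {len(cohort)}", ""]
    counts = pd.Series([r.group for r in cohort]).value_counts()
    total = len(cohort)
    lines += ["## Group counts and sample prevalence", ""]
    for grp, cnt in counts.items():
        lines.append(f"- {grp}: {cnt} ({100 * cnt / total:.1f}%)")
    lines += ["", "## Normative table (normal-cognition group)", ""]
    nd = bundle["norms"].copy()
    for col in ("mean", "sd", "p5", "p10", "retention_pct", "petersen_cutoff"):
        nd[col] = nd[col].map(lambda v: None if pd.isna(v) else round(v, 2))
    lines.append(nd.to_string(index=False))
    norm = bundle["regression_norm"]
    lines += ["", "## Regression-based norming model", "",
              f"expected DSR = {norm.intercept:.3f} + {norm.beta_edu:.3f} x "
              f"education - {abs(norm.beta_age):.3f} x age"
              if norm.beta_age < 0 else
              f"expected DSR = {norm.intercept:.3f} + {norm.beta_edu:.3f} x "
              f"education + {norm.beta_age:.3f} x age",
              f"residual SD = {norm.residual_sd:.3f}; "
              f"R^2 = {norm.r_squared:.3f}; n = {norm.n_fit}",
              "T = 10 x (raw - expected) / residual SD + 50"]
    lines += ["", "## ROC summary", ""]
    rs = bundle["roc_summary"].copy()
    for col in ("auc", "auc_ci_low", "auc_ci_high", "sens", "spec", "youden_j"):
        rs[col] = rs[col].round(3)
    lines.append(rs.to_string(index=False))
    lines += ["", "## Predictive values at assumed base rates", ""]
    lines.append(bundle["pv_grid"].round(3).to_string(index=False))
    rel = bundle["reliability"]
    lines += ["", "## Reliability", ""]
    if rel.get("retest"):
        rt = rel["retest"]
        lines.append(f"- test-retest r = {rt['r']:.3f} (n = {rt['n']}, "
                     f"p = {rt['p_value']:.2e})")
    pc = rel["mmse_dsr_partial"]
    lines.append(f"- MMSE-DSR partial r (controlling age, education) = "
                 f"{pc['r']:.3f} (n = {pc['n']})")
    lines.append("")
    return "\n".join(lines)
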