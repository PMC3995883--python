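"""Run the complete validation pipeline and write a report bundle.

Simulate -> classify -> norms -> T scores -> ROC -> predictive values
-> reliability, with every artifact (CSV/JSON/markdown plus a manifest)
written under one output directory.  Rerunning with the same seed
produces a byte-identical bundle.
"""

from pathlib import Path

from normscreen import PipelineConfig, run_pipeline

config = PipelineConfig(out_dir=Path("report_bundle"), seed=42,
                        make_plots=True)
bundle = run_pipeline(config)

print("artifacts:")
for path in bundle["outputs"]:
    print(" -", path)

rel = bundle["reliability"]
print(f"\ntest-retest r = {rel['retest']['r']:.3f} "
      f"(n = {rel['retest']['n']})")
print(f"MMSE-DSR partial r = {rel['mmse_dsr_partial']['r']:.3f}")
print("\nROC summary:")
print(bundle["roc_summary"].round(3).to_string(index=False))
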