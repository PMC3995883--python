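# Full-pipeline configuration for `normscreen report --config`.
# Either give `input: path/to/cohort.csv` or a `simulate:` block
# (a cohort-spec YAML path, or inline as below with the same schema
# as the packaged data/table1.yaml); omitting both uses the packaged
# default study conditions.
out_dir: report_bundle
seed: 42
age_bands: [[50, 64], [65, 74], [75, 85]]
edu_split: 9
contrasts: [[MCI, NC], [AD, NC]]
base_rates: [0.10, 0.20, 0.30, 0.40, 0.50]
norm_group: NC
make_plots: false
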