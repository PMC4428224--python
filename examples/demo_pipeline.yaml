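# Pipeline over the dataset written by:
#   modconn simulate --config examples/demo_design.yaml --out demo_data
timeseries_dir: demo_data
parcellation_file: demo_data/parcellation.csv
group_file: demo_data/groups.csv
behavior_file: demo_data/behavior.csv
output_dir: demo_out
group_names: [MEDT, CTRL]
z_threshold: 3.0
d_threshold: 0.5
retention_threshold: 0.05
consistency_threshold: 0.33
r_threshold: 0.5
n_folds: 4
seed: 42
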