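# Full-pipeline configuration: simulate a four-group cohort and analyze it.
seed: 1
outdir: zfsleep_out
schedule:
  lights_on: "08:00"
  lights_off: "22:00"
  recording_start: "13:00"
sleep_window: ["22:00", "08:00"]
scoring:
  movement_threshold: 1.0   # mm/s
  sleep_period_threshold: 6 # s
simulate:
  n_per_group: 30
  duration_s: 86400
  sample_rate: 25
  groups: [group1, group2, group3, group4]
control_label: group1
stats:
  alpha: 0.05
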