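# Example pipeline configuration for a synthetic run.
# For recorded data, replace the `simulation` block with:
#   data:
#     metadata: path/to/metadata.csv
#     samples:  path/to/samples.csv

seed: 7

simulation:
  n_participants: 24
  n_trials_per_condition: 32
  # rt_base, rt_offsets, pull_prob, pull_amplitude etc. default to the
  # published-study calibration; override any field here.

clustering:
  k: 8
  x_threshold: 0.05
  linkage: ward

inference:
  ci_global: 0.99   # component CIs
  ci_step: 0.95     # per-time-step CIs
  min_run: 10       # consecutive significant steps required for reporting

timecourse:
  components: [total_stroop, interference, facilitation]
  measures: [deviation, x_coordinate]
  slope: auto
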