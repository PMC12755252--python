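# Mean residence time vs gamma-delay CV for the co-repressive toggle
# switch, at reduced replication.  Run:
#   grnswitch sweep-cv --config examples/toggle_sweep.yaml --out results/toggle
experiment: cv_sweep
model:
  name: toggle
kernel:
  family: gamma
  mean: 3.0
sweep:
  cv_grid: [0.0, 0.3, 1.0, 2.0]
stop:
  min_residences: 24
  max_events: 4.0e+9
seeds: [31, 32]
regions:
  radius_frac: 0.85
  iband_frac: 0.5
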