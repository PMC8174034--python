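# Desk-scale configuration: a complete pipeline run in a few minutes on
# one CPU. Analysis parameters keep their protocol defaults; only the
# cohort size and the decoder's resampling counts are reduced.
out_dir: runs/demo
seed: 1
min_spikes_per_unit: 500
simulate:
  n_mice_per_group: 3
  units_per_mouse: 4
decoding:
  n_runs: 10
  n_nulls: 2
  step_ms: 1000.0
  n_per_class_cap: 15
  alignments: [press_offset]
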