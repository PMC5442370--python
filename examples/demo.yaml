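# Small demonstration cohort: 12 subjects, strong distributed spindle
# signature in the first two 90-min segments of NREM sleep.
seed: 3
n_perm: 99
perm_reps: 2
out_dir: results/demo
sim:
  n_subjects: 12
  n_groups: 8
  night_duration_min: 180
  signature_amplitude: 0.6
  signature_cells: [[2, spindle], [5, spindle], [7, spindle]]
  signature_segments: [1, 2]
  seed: 3
decode:
  n_reps: 10
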