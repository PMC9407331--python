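# Five-variety synthetic demonstration cohort: target ratios span the
# range observed for mandarin varieties, acceptabilities follow the
# sensory panel scores of the reference study.
output_dir: citrusnmr_demo_out
seed: 1
windows: auto
simulation:
  schemes: [high_field, benchtop]
  n_replicates: 5
  varieties:
    - {variety_id: V1, target_ratio: 9.31, acceptability: 7.4}
    - {variety_id: V2, target_ratio: 10.12, acceptability: 6.9}
    - {variety_id: V3, target_ratio: 7.70, acceptability: 5.5}
    - {variety_id: V4, target_ratio: 6.34, acceptability: 4.8}
    - {variety_id: V5, target_ratio: 4.16, acceptability: 3.6}
processing:
  zero_fill_to: 65536
  exponential_lb: 0.3
  phase_mode: auto
  baseline_mode: iterative
  reference_target: 5.22
  alignment: derivative_mean_reference
  max_shift: 0.05
  segment_mode: whole
weights:
  sucrose: 1.0
  fructose: 1.3
  glucose: 0.6
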