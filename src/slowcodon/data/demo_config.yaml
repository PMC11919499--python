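cells:
  n_cells: 30
final_sample_time: 20000.0
n_cells_per_condition: 30
outdir: demo_out
seed: 0
select_sample_time: 2000.0
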