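# Desk-scale end-to-end run: ~200 synthetic records, quarter-width model.
# Usage:  ppgbp run-all --config quickstart.yaml --out-dir quickstart_run
seed: 0
out_dir: quickstart_run
sim:
  n_records: 200
  duration_s: 10.0
  preset: uniform
  drift_amp: 0.0
  powerline_amp: 0.0
  noise_sd: 0.0
preprocess:
  window_s: 3.0
  ac_threshold: 0.6
model:
  width_multiplier: 0.25
train:
  loss: huber
  delta: 1.0
  epochs: 15
  batch_size: 64
  lr0: 0.05
  split: [0.7, 0.1, 0.2]
evaluate:
  plots: false
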