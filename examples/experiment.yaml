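# Desk-scale six-condition cross-device experiment.
# Run with: meibseg run-experiment --config examples/experiment.yaml --out runs/demo
internal_style: deviceA
external_style: deviceB
conditions:
  - internal
  - internal+clahe
  - external
  - external+hs
  - external+clahe
  - external+hs+clahe
n_train: 30
n_val: 6
n_test_internal: 10
n_test_external: 10
augment: false          # true expands the training set 12-fold (slow on CPU)
seed: 0
model:
  width_scale: 0.25     # 1.0 = full capacity
  input_size: 96
training:
  max_epochs: 10
  batch_size: 8
  input_size: 96
clahe_params:
  tile_size: 64
  clip_limit: 2.0
out_dir: runs/demo
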