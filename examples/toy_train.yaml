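# Desk-scale training configuration (32x32 phantoms, CPU-friendly).
# The reference-scale defaults (128x128, width 32, 300 epochs, 50:1 warm-up)
# are the TrainConfig defaults; everything here is deliberately small.
epochs: 6
batch_size: 8
warmup_epochs: 1
critic_updates_warmup: 10
critic_updates_main: 3
learning_rate: 0.0002
weight_decay: 0.0001
betas: [0.9, 0.999]
crop_pixels_x: 90
target_size: 32
gap_min: -25.0
gap_max: 25.0
lambda_gp: 10.0
lambda_cc: 1.0
augment: true
covariate: age
steps_per_epoch: 8
seed: 7
net:
  image_size: 32
  base_width: 8
  channel_mults: [1, 2]
  blocks_per_level: 1
  attention_resolutions: [8]
  embed_dim: 16
  cond_hidden: 32
  groups: 4
  covariate_scale: 1.0
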