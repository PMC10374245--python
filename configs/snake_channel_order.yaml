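# Example run configuration demonstrating an explicit channel reordering.
# `preprocess.channel_order` lists, for each output row, the input channel
# index to place there. This example is the boustrophedon ("snake") order
# for a 40-channel montage laid out as 5 rows of 8: row 0 left-to-right,
# row 1 right-to-left, and so on, so that adjacent rows of the model's
# channel-axis convolutions see spatially adjacent channels.
# Generated with: dbjnet.snake_channel_order(40, 8).
sim:
  n_subjects: 18
  n_blocks: 2
  trials_per_block: 12
  class_mix_per_block:
  - 3
  - 6
  - 3
  n_channels: 40
  fs: 4.0
  video_duration_s: 60.0
  rest_s: 15.0
  effect_amplitude: 1.0
  pattern_overlap: 0.3
  subject_gain_sd: 0.2
  pattern_jitter_sd: 0.4
  noise:
    white: 0.3
    mayer: 0.3
    respiration: 0.15
    cardiac: 0.1
    drift: 0.5
    mayer_hz: 0.1
    respiration_hz: 0.3
    cardiac_hz: 1.1
  hrf:
    peak_delay_s: 6.0
    undershoot_delay_s: 16.0
    dispersion: 1.0
    undershoot_ratio: 0.16666666666666666
    duration_s: 32.0
  seed: 0
preprocess:
  band_low_hz: 0.01
  band_high_hz: 0.5
  filter_order: 3
  baseline_s: 5.0
  window_s: 40.0
  zero_phase: true
  channel_order:
  - 0
  - 1
  - 2
  - 3
  - 4
  - 5
  - 6
  - 7
  - 15
  - 14
  - 13
  - 12
  - 11
  - 10
  - 9
  - 8
  - 16
  - 17
  - 18
  - 19
  - 20
  - 21
  - 22
  - 23
  - 31
  - 30
  - 29
  - 28
  - 27
  - 26
  - 25
  - 24
  - 32
  - 33
  - 34
  - 35
  - 36
  - 37
  - 38
  - 39
model:
  n_channels: 40
  n_samples: 160
  conv1_kernels: 32
  conv1_size: 8
  conv1_stride: 4
  conv2_kernels: 64
  conv2_size: 4
  conv2_stride: 2
  pool_out:
  - 8
  - 8
  cnn_embed_dim: 256
  stat_fc_dims:
  - 64
  - 128
  - 256
  n_classes: 3
  use_cnn_branch: true
  use_stat_branch: true
  init_seed: 0
train:
  lr_init: 0.0001
  plateau_patience: 14
  lr_decay_factor: 0.9
  batch_size: 32
  max_epochs: 200
  early_stop_patience: 30
  seed: 0
  class_weighting: false
tasks:
- pos_neu_neg
out_dir: results
log_level: INFO
master_seed: 0
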