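# Desk-scale design configuration: 16 rings / 4x DoF target on 64x64 scenes.
# Lengths in micrometres. See docs/methods.md for the rationale behind each
# value; the full-scale defaults (64 rings, 16x target) live in
# bpfscope.config.TrainConfig.
optics:
  na: 0.75
  wavelength: 0.525
  magnification: 33.333333333333336
  pixel_pitch: 6.5
  n_medium: 1.0
  grid_size: 64
train:
  k_rings: 16
  target_dof_factor: 4.0
  epochs: 10
  steps_per_epoch: 20
  finetune_steps: 100
  batch_size: 8
  learning_rate: 0.002
  phase_learning_rate: 0.02
  noise_sigma: 0.05
  net_depth: 3
  net_base_channels: 16
  init_kind: axicon
  init_param: 3.141592653589793
eval:
  ssim_thr: 0.900
  z_min: -8.0
  z_max: 8.0
  z_step: 0.5
  dataset_size: 8
seed: 1
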