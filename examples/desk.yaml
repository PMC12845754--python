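# Desk-scale experiment: 4 subjects, 16 channels, subject-specific selection.
synthetic:
  n_subjects: 4
  n_channels: 16
  fs: 160.0
  runs_per_subject: 14
  run_duration_s: 30.0
  n_planted: 4
  snr: 8.0
  seed: 1
  task_modulation:
    rest: 0.3
    motor_execution: 1.0
    motor_imagery: 0.7
budget: 4
strategy: subject_specific
backbone:
  n_blocks: 1
  lr: 0.02
  batch_size: 128
  max_epochs: 40
  patience: 40
cma:
  conv_channels: [32, 32, 32]
  n_layers: 1
  lr: 0.02
  batch_size: 128
  max_epochs: 10
  patience: 10
n_folds: 1
repetitions: 1
seed: 1
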