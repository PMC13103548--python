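# Default MDEFusion recipe with the reference hyperparameters pinned.
seed: 0
out_dir: run

simulate:
  preset: nnci-like        # 16-channel, 60 s recordings; use repod-like for 19-channel, 900 s
  band: alpha
  power_ratio: 3.0
  corr_shift: 0.2
  noise_sd: 1.0

preprocess:
  low: 0.0                 # band-limit lower edge (0 => pure low-pass)
  high: 100.0              # clamped below Nyquist at low sampling rates
  win_s: 2.0
  stride_s: 1.0
  train_frac: 0.8          # remaining subjects split equally val/test
  harmonize: true          # 16-channel montages -> unified 19-channel set

features:
  mode: wpt
  wavelet: db4
  depth: 3
  ica_max_samples: 50000

hcsae:
  abstract_channels: 32
  n_1x3_layers: 2
  dropout_q: 0.3
  latent_channels: 64
  recon_weight: 0.1

balstm:
  hidden: 64               # hidden-layer nodes
  layers: 3                # bidirectional 3-layer stack

train:
  lr: 0.001
  batch: 64
  epochs: 200
  decay: 0.9               # learning rate x0.9 ...
  decay_every: 20          # ... every 20 epochs
  seq_len: 32              # temporal condensation entering the network

evaluate:
  subject_threshold: 0.95  # strict: > 95% of a subject's segments correct
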