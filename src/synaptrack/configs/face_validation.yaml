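# Canonical face-validation design: 18 windows (9 pre-onset + 9 post-onset,
# 1-s spacing, 2-s windows) of two-channel complex CSD over 8-48 Hz, generated
# from the two-source model with mono-exponentially decaying excursions
# (intrinsic time constant 8 s, extrinsic 2 s) at signal-to-noise ratio 4.
n_pre: 9
n_post: 9
step_s: 1.0
window_s: 2.0
f_lo: 8.0
f_hi: 48.0
snr: 4.0
tau_intrinsic_s: 8.0
tau_extrinsic_s: 2.0
amplitudes:
  intrinsic_primary: 2.0
  intrinsic_secondary: 2.0
  forward: 1.0
architecture: forward
basis_order: 3
seed: 1
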