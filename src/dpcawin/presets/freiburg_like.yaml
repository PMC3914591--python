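# Two-class long-record preset: interictal vs ictal-like activity with
# matched average power (each class's AR(2) part is normalised to RMS 1 via
# target_rms) but distinct spectral peaks.  Energy alone cannot separate
# these classes; the within-window correlation structure can.
name: freiburg_like
sample_rate: 256.0
signal_length: 16384
n_signals_per_class: 8
seed: 20140116
classes:
  - label: interictal
    center_frequency: 12.0
    bandwidth: 0.5
    target_rms: 1.0
    spike_rate: 0.0
    spike_amplitude: 0.0
    noise_sd: 0.3
  - label: ictal
    center_frequency: 4.0
    bandwidth: 0.5
    target_rms: 1.0
    spike_rate: 0.0
    spike_amplitude: 0.0
    noise_sd: 0.3
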