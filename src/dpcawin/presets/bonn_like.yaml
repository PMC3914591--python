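# Five-class single-channel short-segment preset.
# Classes mimic, qualitatively: relaxed eyes-open (A) and eyes-closed (B)
# normal rhythms; interictal activity recorded outside (C) and inside (D)
# the epileptogenic zone, with spike transients; and a high-power
# low-frequency ictal rhythm (E).  Class power ordering by construction:
# E >> D >> normals, with C's power kept close to the normal classes so its
# separation must come from spectral/spike structure, not energy.
name: bonn_like
sample_rate: 173.61
signal_length: 4096
n_signals_per_class: 20
seed: 20140116
classes:
  - label: A
    center_frequency: 10.0
    bandwidth: 4.0
    amplitude_scale: 1.0
    spike_rate: 0.0
    spike_amplitude: 0.0
    noise_sd: 0.5
  - label: B
    center_frequency: 9.0
    bandwidth: 3.0
    amplitude_scale: 1.1
    spike_rate: 0.0
    spike_amplitude: 0.0
    noise_sd: 0.5
  - label: C
    center_frequency: 7.0
    bandwidth: 3.0
    amplitude_scale: 0.8
    spike_rate: 0.3
    spike_amplitude: 4.0
    noise_sd: 0.5
  - label: D
    center_frequency: 6.0
    bandwidth: 3.0
    amplitude_scale: 1.6
    spike_rate: 0.8
    spike_amplitude: 6.0
    noise_sd: 0.5
  - label: E
    center_frequency: 4.0
    bandwidth: 1.5
    amplitude_scale: 5.0
    spike_rate: 0.0
    spike_amplitude: 0.0
    noise_sd: 0.5
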