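# Demo study: 3 etiology groups x 5 subjects x 2 anesthesia states, 60 s of
# 19-channel EEG at 2,000 Hz per recording. Runs end to end in a few minutes.
seed: 7
simulate:
  n_per_group: 5
  groups: [AIE, CVA, TBI]
  states: [baseline, steady_state]
  duration_s: 60
  fs: 2000
preprocess:
  highpass_cutoff: 0.1
  highpass_order: 3300
  lowpass_cutoff: 45
  lowpass_order: 1500
  target_fs: 100
  amp_thresh: 150
  grad_thresh: 50
  badchan_z: 3.0
entropy:
  m: 6
  tau: 1
  band: [7, 12]
spectral:
  window_s: 5
  overlap_s: 2.5
  time_bandwidth: 3
  n_tapers: 5
stats:
  alpha: 0.05
  lmm_region: prefrontal
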