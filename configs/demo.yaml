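# Reduced end-to-end demo: 8 subjects, 250 Hz, 20 trials per session.
# Runs the full pipeline (simulate -> preprocess -> coherence -> networks ->
# differential statistics -> behavior) in well under two minutes.
mode: simulate
seed: 42
design:
  n_subjects: 8
  n_sessions: 2
  n_trials_per_session: 20
  sampling_rate: 250.0
  epoch_duration: 3.0
  baseline_duration: 0.1
noise_sd: 10.0
couplings:
  - band: theta
    edge: [F3, Fz]
    coupling_session1: 0.15
    coupling_session2: 0.45
    subject_sd: 0.05
  - band: alpha
    edge: [Fp2, O1]
    coupling_session1: 0.2
    coupling_session2: 0.5
    subject_sd: 0.05
behavior:
  accuracy_session1: 0.7
  accuracy_session2: 0.9
  rt_mean_session1: 1.0
  rt_mean_session2: 0.8
  rt_sd: 0.25
  max_time: 2.0
bands: [theta, alpha, beta, full]
diff_bands: [theta, alpha, beta]
welch:
  window_s: 1.0
  overlap: 0.5
  shape: hann
preprocess:
  low_hz: 0.5
  high_hz: 45.0
  baseline: [-0.1, 0.0]
  reject_uv: 100.0
  rereference: true
network:
  threshold: auto
  n_random: 20
diffnet:
  alpha_level: 0.05
  fdr: bh
  hub_rule: sd
  hub_sd_factor: 1.0
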