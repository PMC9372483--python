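{
  "modulation": {
    "lambda_attention": 0.5,
    "lambda_pace": 0.5,
    "beta_internal": 1.0,
    "beta_external": 4.0,
    "f_min_hz": 3.0,
    "f_max_hz": 5.0,
    "pace_scale": 0.15,
    "gamma_word_final": 1.2,
    "gamma_utterance_final": 1.5
  },
  "coupling": {
    "attract": 1.0,
    "repel": 10.0
  },
  "oscillator": {
    "amp_threshold": 0.5,
    "amp_response_s": 0.05,
    "base_phase": 3.141592653589793
  },
  "feedback": {
    "tau_open": 0.25,
    "tau_close": 0.29,
    "alpha_int_pair": 2.127659574468085,
    "alpha_ext_pair": 10.0,
    "alpha_int_final": 4.166666666666667,
    "alpha_ext_final": 15.0,
    "alpha_int_C": 2.5,
    "alpha_int_R": 4.166666666666667,
    "tau_final": 0.25,
    "delay_s": 0.1
  },
  "fig8": {
    "link_tau": 0.15,
    "start_tau": 0.05,
    "close_tau": 0.5,
    "independent_taus": [0.1, 0.25, 0.4],
    "osc_freq_hz": 4.0,
    "osc_attract": 100.0,
    "osc_repel": 200.0
  }
}
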