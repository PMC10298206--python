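{
  "phi": 2417.2,
  "K": 1200.0,
  "sigma": 0.42,
  "a_star": 834.16,
  "vc": 6.2e-06,
  "p": 0.54,
  "n": 0.799,
  "b_star": 5821.0,
  "d": 0.406,
  "eta": 2485.0,
  "r": 0.002448,
  "omega": 2.4,
  "delta": 3e-13,
  "q": 7.6258e-13,
  "v": 5.0,
  "h0": 3.98e-14,
  "h_thresh": 2e-13,
  "alpha": 0.1,
  "beta": 0.1,
  "zeta": 1e-05
}
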