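{
  "s0_10": 0.9281037940401093,
  "beta_c": 0.39047877029682926,
  "beta_mp": 0.3690436472981232,
  "beta_ot": 0.44993556006586627,
  "hr_chemo": 0.64,
  "rho_c_mp": 0.6552543459641662,
  "rho_c_ot": 0.49570081823438655,
  "rho_mp_ot": 0.7364716092942295,
  "mp_latent_cutoff": 0.42424441374860217,
  "clinical_high_cutoff": -0.0025066308995717666,
  "ot_a": 0.25000000000322953,
  "ot_b": 1.7790980063505988,
  "mu_c": 0.0,
  "sigma_c": 1.0
}
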