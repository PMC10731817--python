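{
  "model_type": "FmLogisticModel",
  "version": 1,
  "description": "Logistic classifier for absent fidgety movements from resultant COP velocity variability and approximate entropy",
  "beta0": -3.354,
  "beta_iv": -0.010,
  "beta_apen": 0.895,
  "threshold": 0.15,
  "se_beta0": 1.336,
  "se_iv": 0.005,
  "se_apen": 0.294
}
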