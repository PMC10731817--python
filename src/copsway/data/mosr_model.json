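{
  "model_type": "MosrLinearModel",
  "version": 1,
  "description": "Log-linear estimator of the Motor Optimality Score-Revised from resultant COP parameters",
  "a0": 1.294,
  "a_iv_std": 0.172,
  "a_iv_skew": -0.219,
  "a_apen": -0.265,
  "log_base": 10.0,
  "score_range": [5.0, 28.0]
}
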