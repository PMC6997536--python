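{
  "auc": 0.9873684210526316,
  "f_at_0.05": 0.8000000000000002,
  "f_at_0.1": 0.5333333333333333,
  "f_at_0.2": 0.4,
  "f_at_1": 0.09523809523809523,
  "mean_f": 0.2563475038855207,
  "n": 100,
  "pauc_90": 0.08736842105263155,
  "pr_auc": 0.8909090909090909,
  "prevalence": 0.05,
  "sens_at_90": 1.0
}
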