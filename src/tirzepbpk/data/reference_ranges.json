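{
  "description": "Adult reference exposure ranges after a single 5 mg SC dose of tirzepatide, used as the matching target for pediatric dose selection.",
  "auc_0_168_ng_h_per_ml": [43459, 63467],
  "cmax_ng_per_ml": [305.7, 488.3],
  "tmax_h": [24, 72]
}
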