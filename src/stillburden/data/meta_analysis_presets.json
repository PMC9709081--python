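{
  "zhang2021": {
    "description": "Pooled odds ratio for stillbirth per 10 ug/m3 PM2.5 from the Zhang et al. (2021) meta-analysis of seven studies.",
    "or_per_10": 1.103,
    "ci_lo": 1.074,
    "ci_hi": 1.131
  },
  "xie2021": {
    "description": "Pooled odds ratio for stillbirth per 10 ug/m3 PM2.5 from the Xie et al. (2021) meta-analysis of six studies.",
    "or_per_10": 1.15,
    "ci_lo": 1.07,
    "ci_hi": 1.25
  }
}
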