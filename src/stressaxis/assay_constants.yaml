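# Versioned study constants for hormone scoring.
version: 1
lh_surge:
  threshold_ng_ml: 3.8        # mean + 3 SD of proestrous 0 h LH
  sd_multiplier: 3
  strict: true                # surge iff any PM value is strictly above
assay_ranges:
  LH:
    lower_ng_ml: 0.16         # 1:10 dilution of the 0.016-4.0 ng/ml range
    upper_ng_ml: 40.0
  corticosterone:
    lower_ng_ml: 3.9
    upper_ng_ml: 1000.0
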