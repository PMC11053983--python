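{
  "theta1_CL": 0.693,
  "theta2_CL_exp": 0.785,
  "theta3_V1": 3.96,
  "theta4_Q2": 4.45,
  "theta5_V2": 8.24,
  "theta6_Q3": 1.76,
  "theta7_V3": 69.8,
  "theta8_V3_exp": 1.73,
  "egfr_ref": 105.27,
  "wt_ref": 67.85,
  "iiv_cv": {
    "CL": 0.0883,
    "V1": 0.238,
    "Q2": 0.327,
    "V2": 0.239,
    "Q3": 0.310,
    "V3": 0.0754
  },
  "prop_error_cv": 0.0633
}
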