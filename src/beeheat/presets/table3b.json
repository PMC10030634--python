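{
 "name": "table3b",
 "variant": "three_compartment_reduced",
 "coefficients": {
  "r_l": 0.33816,
  "r_g": 0.06758,
  "e_lev": -8.71008,
  "a_hthhd": -0.00167,
  "b_hthhd": 0.000234,
  "a_hth": 20.85664,
  "b_hth": 0.38344,
  "h_thab": 0.00195
 },
 "t_values": {
  "r_l": 1.86167,
  "r_g": 5.31464,
  "e_lev": -2.49426,
  "a_hthhd": -3.0797,
  "b_hthhd": 10.66662,
  "a_hth": 3.98683,
  "b_hth": 1.63488,
  "h_thab": 11.56947
 },
 "p_gt_t": {
  "r_l": 0.06299,
  "r_g": 1.36e-07,
  "e_lev": 0.01281,
  "a_hthhd": 0.00214,
  "b_hthhd": 0.0,
  "a_hth": 7.26e-05,
  "b_hth": 0.10244,
  "h_thab": 0.0
 },
 "statistics": {
  "sd_res_mW": 5.78,
  "adj_r2": 0.89097,
  "n": 872,
  "df": 864,
  "F": 9729.44757
 },
 "units_note": "r_l, r_g, e_lev dimensionless; a_hth/b_hth in W m-2 degC-1/-2 (thorax term carries the area factor); head and abdomen coefficients are absolute: a_* in W degC-1, b_* in W degC-2.",
 "provenance": "Published coefficient sets for the stationary-forager heat-exchange model, transcribed from the source tables.",
 "caveat": "The flattened source tables show transcription ambiguities (the e_lev values -7.80027 / -8.71008 / -8.61143 overlap across columns, and -8.71008 also appears as b_hhd); values are entered exactly as printed."
}
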