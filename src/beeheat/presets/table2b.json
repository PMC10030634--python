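{
 "name": "table2b",
 "variant": "per_part_reduced",
 "coefficients": {
  "r_l": 0.33816,
  "r_g": 0.06758,
  "e_lev": -7.80027,
  "a_hhd": 55.80168,
  "b_hhd": -8.71008,
  "a_hth": 26.57184,
  "b_hth": 5.28199,
  "h_ab": -22.66916
 },
 "t_values": {
  "r_l": 1.86167,
  "r_g": 5.31464,
  "e_lev": -10.66662,
  "a_hhd": 3.0797,
  "b_hhd": -2.49426,
  "a_hth": 3.17143,
  "b_hth": 15.86683,
  "h_ab": -11.56947
 },
 "p_gt_t": {
  "r_l": 0.06299,
  "r_g": 1.36e-07,
  "e_lev": 0.0,
  "a_hhd": 0.00214,
  "b_hhd": 0.01281,
  "a_hth": 0.00157,
  "b_hth": 0.0,
  "h_ab": 0.0
 },
 "statistics": {
  "sd_res_mW": 5.78,
  "adj_r2": 0.89097,
  "n": 872,
  "df": 864,
  "F": 9729.44757
 },
 "units_note": "r_l, r_g, e_lev dimensionless; a_hxx in W m-2 degC-1, b_hxx in W m-2 degC-2 (h_ab in W m-2 degC-1).",
 "provenance": "Published coefficient sets for the stationary-forager heat-exchange model, transcribed from the source tables.",
 "caveat": "The flattened source tables show transcription ambiguities (the e_lev values -7.80027 / -8.71008 / -8.61143 overlap across columns, and -8.71008 also appears as b_hhd); values are entered exactly as printed."
}
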