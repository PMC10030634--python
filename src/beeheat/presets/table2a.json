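{
 "name": "table2a",
 "variant": "per_part",
 "coefficients": {
  "r_l": 0.33306,
  "r_g": 0.06799,
  "e_lev": -8.61143,
  "a_hhd": 51.73447,
  "b_hhd": -7.62225,
  "a_hth": 26.88355,
  "b_hth": 5.26661,
  "a_hab": -21.14844,
  "b_hab": -0.06052
 },
 "t_values": {
  "r_l": 1.81631,
  "r_g": 5.28299,
  "e_lev": -2.4425,
  "a_hhd": 1.94636,
  "b_hhd": -6.79265,
  "a_hth": 3.15739,
  "b_hth": 15.43998,
  "a_hab": -2.80945,
  "b_hab": -0.20924
 },
 "p_gt_t": {
  "r_l": 0.06967,
  "r_g": 1.61e-07,
  "e_lev": 0.01479,
  "a_hhd": 0.05194,
  "b_hhd": 2.05e-11,
  "a_hth": 0.00165,
  "b_hth": 0.0,
  "a_hab": 0.00507,
  "b_hab": 0.83431
 },
 "statistics": {
  "sd_res_mW": 5.78,
  "adj_r2": 0.89085,
  "n": 872,
  "df": 863,
  "F": 8638.83122
 },
 "units_note": "r_l, r_g, e_lev dimensionless; a_hxx in W m-2 degC-1, b_hxx in W m-2 degC-2 (h_ab in W m-2 degC-1).",
 "provenance": "Published coefficient sets for the stationary-forager heat-exchange model, transcribed from the source tables.",
 "caveat": "The flattened source tables show transcription ambiguities (the e_lev values -7.80027 / -8.71008 / -8.61143 overlap across columns, and -8.71008 also appears as b_hhd); values are entered exactly as printed."
}
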