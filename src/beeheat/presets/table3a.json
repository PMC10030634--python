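{
 "name": "table3a",
 "variant": "three_compartment",
 "coefficients": {
  "r_l": 0.33306,
  "r_g": 0.06799,
  "e_lev": -8.61143,
  "a_hthhd": -0.00155,
  "b_hthhd": 0.000229,
  "a_hth": 21.34836,
  "b_hth": 0.37104,
  "a_hthab": 0.00182,
  "b_hthab": 5.2e-06
 },
 "t_values": {
  "r_l": 1.81631,
  "r_g": 5.28299,
  "e_lev": -2.4425,
  "a_hthhd": -1.94636,
  "b_hthhd": 6.79265,
  "a_hth": 3.72077,
  "b_hth": 1.53302,
  "a_hthab": 2.80945,
  "b_hthab": 0.20924
 },
 "p_gt_t": {
  "r_l": 0.06967,
  "r_g": 1.61e-07,
  "e_lev": 0.01479,
  "a_hthhd": 0.05194,
  "b_hthhd": 2.05e-11,
  "a_hth": 0.000211,
  "b_hth": 0.12564,
  "a_hthab": 0.00507,
  "b_hthab": 0.83431
 },
 "statistics": {
  "sd_res_mW": 5.78,
  "adj_r2": 0.89085,
  "n": 872,
  "df": 863,
  "F": 8638.83122
 },
 "units_note": "r_l, r_g, e_lev dimensionless; a_hth/b_hth in W m-2 degC-1/-2 (thorax term carries the area factor); head and abdomen coefficients are absolute: a_* in W degC-1, b_* in W degC-2.",
 "provenance": "Published coefficient sets for the stationary-forager heat-exchange model, transcribed from the source tables.",
 "caveat": "The flattened source tables show transcription ambiguities (the e_lev values -7.80027 / -8.71008 / -8.61143 overlap across columns, and -8.71008 also appears as b_hhd); values are entered exactly as printed."
}
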