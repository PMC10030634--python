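{
 "name": "simple",
 "variant": "simple",
 "coefficients": {
  "r_l": 0.68114,
  "r_g": 0.30352,
  "e_lev": 1.82501,
  "h_b": 12.14393
 },
 "t_values": {},
 "p_gt_t": {},
 "statistics": {
  "sd_res_mW": 15.3,
  "adj_r2": 0.24078,
  "n": 872
 },
 "units_note": "r_l, r_g, e_lev dimensionless; h_b in W m-2 degC-1.",
 "provenance": "Published coefficient sets for the stationary-forager heat-exchange model, transcribed from the source tables.",
 "caveat": "The flattened source tables show transcription ambiguities (the e_lev values -7.80027 / -8.71008 / -8.61143 overlap across columns, and -8.71008 also appears as b_hhd); values are entered exactly as printed."
}
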