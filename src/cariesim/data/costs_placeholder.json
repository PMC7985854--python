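{
 "ai_fee_per_bitewing_pair": 8.0,
 "currency": "EUR-2020",
 "fees": {
  "crown": 361.59,
  "direct_capping": 32.13,
  "exam_bw": 12.16,
  "exam_vt": 13.1,
  "extraction": 31.01,
  "implant_iscrown": 1637.79,
  "infiltration": 71.23,
  "nonsurg_retreat": 300.41,
  "rct": 359.42,
  "re_restoration": 141.6,
  "recement": 23.15,
  "recrown": 373.51,
  "refix": 55.9,
  "reimplant": 1305.39,
  "repair": 67.38,
  "restoration": 105.74,
  "surg_retreat": 328.61
 },
 "shared_divisor": 16,
 "synthetic": true
}
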