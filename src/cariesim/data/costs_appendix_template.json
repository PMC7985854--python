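{
 "ai_fee_per_bitewing_pair": 8.0,
 "currency": "EUR-2020",
 "fees": {
  "crown": 0.0,
  "direct_capping": 0.0,
  "exam_bw": 0.0,
  "exam_vt": 0.0,
  "extraction": 0.0,
  "implant_iscrown": 0.0,
  "infiltration": 0.0,
  "nonsurg_retreat": 0.0,
  "rct": 0.0,
  "re_restoration": 0.0,
  "recement": 0.0,
  "recrown": 0.0,
  "refix": 0.0,
  "reimplant": 0.0,
  "repair": 0.0,
  "restoration": 0.0,
  "surg_retreat": 0.0
 },
 "shared_divisor": 16,
 "synthetic": false
}
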