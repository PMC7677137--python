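{
 "schema": "hlamatch/allele-codes v1",
 "comment": "Synthetic example multiple-allele code table illustrating the expected schema; real NMDP tables can be dropped in with the same structure.",
 "codes": {
  "A*34:AB": ["A*34:01", "A*34:02"],
  "B*07:AC": ["B*07:02", "B*07:05", "B*07:06"],
  "DRB1*15:AB": ["DRB1*15:01", "DRB1*15:03"]
 }
}
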