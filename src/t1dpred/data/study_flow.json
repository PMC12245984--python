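{
  "screened": 4377,
  "excluded_hyperglycaemia": 355,
  "excluded_incomplete": 55,
  "progressed": 1311
}
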