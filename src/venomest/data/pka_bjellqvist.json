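{
  "name": "bjellqvist",
  "version": "1.0",
  "positive": {
    "K": 10.0,
    "R": 12.0,
    "H": 5.98
  },
  "negative": {
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0
  },
  "nterm_default": 7.5,
  "nterm_by_residue": {
    "A": 7.59,
    "M": 7.0,
    "S": 6.93,
    "P": 8.36,
    "T": 6.82,
    "V": 7.44,
    "E": 7.7
  },
  "cterm_default": 3.55,
  "cterm_by_residue": {
    "D": 4.55,
    "E": 4.75
  }
}
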