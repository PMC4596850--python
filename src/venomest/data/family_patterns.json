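{
  "families": {
    "A": "-Cx7-Cx8-CCx4-Cx5-CCx3-Cx3-Cx17-C-",
    "B": "-Cx6C-CC-CxC-CxC-",
    "C": "-Cx6-Cx3-Cx-CCx6-Cx5-Cx7-Cx6-Cx6-C-",
    "D": "Cx6-Cx6-CCx4/8-CxC-x6/7-CxC-",
    "E": "-Cx6-Cx3-Cx-CC-x5-CxC-x10-CxC-x7-Cx6-Cx7-Cxn-",
    "F": "-Cx6-Cx3/4-Cx-CC-x5/6-CxC-x6/7-CxC-x7-Cx6-Cx6/12-Cxn-",
    "G": "-Cx5-Cx4-CC-x8-C-x9-C-x12-CxC-x5-C-x5-C-",
    "H": "Cx5-Cx4-CC-x10-Cx9-Cx16-CxC-x5-Cx18-Cxn"
  },
  "mizhoanus_specific_skeletons": [
    "C-CXC-CXC-CXC-C-C-C",
    "C-C-C-CC-CXC-CXC-C"
  ],
  "category_counts": {
    "toxin": 190,
    "cellular": 65,
    "unknown": 12
  }
}
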