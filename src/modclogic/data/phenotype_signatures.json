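{
 "marker_sets": {
  "moDC": [
   "TLR8",
   "TLR7",
   "TLR6",
   "TLR4",
   "TLR3",
   "NCOR2",
   "LY75",
   "CLEC4A",
   "CD83",
   "CD48",
   "CD226",
   "CD209",
   "CD1C",
   "CD1B",
   "CD1A",
   "THBD",
   "ITGAX",
   "CCL22",
   "CCL2"
  ],
  "monocyte": [
   "CD14",
   "SELL"
  ],
  "macrophage": [
   "CD163",
   "CCDC151",
   "MERTK",
   "CD206"
  ]
 },
 "signatures": {
  "death": {
   "inputs": {
    "CSF2": 0,
    "IL4": 0
   },
   "on": [],
   "off": [
    "TLR8",
    "TLR7",
    "TLR6",
    "TLR4",
    "TLR3",
    "NCOR2",
    "LY75",
    "CLEC4A",
    "CD83",
    "CD48",
    "CD226",
    "CD209",
    "CD1C",
    "CD1B",
    "CD1A",
    "THBD",
    "ITGAX",
    "CCL22",
    "CCL2",
    "CD14",
    "SELL",
    "CD163",
    "CCDC151",
    "MERTK",
    "CD206",
    "KLF4",
    "IRF4",
    "MAFB"
   ],
   "exact": {}
  },
  "monocyte": {
   "on": [
    "KLF4",
    "SELL",
    "CD14"
   ],
   "off": [
    "IRF4",
    "MAFB",
    "CD1A",
    "CD209",
    "CD206",
    "CCDC151"
   ],
   "exact": {}
  },
  "macrophage": {
   "on": [
    "MAFB",
    "IRF8",
    "CCDC151",
    "CD206"
   ],
   "off": [
    "KLF4",
    "IRF4",
    "SELL",
    "CD14",
    "CD1A",
    "CD209"
   ],
   "exact": {}
  },
  "moDC": {
   "on": [
    "IRF4",
    "STAT6",
    "CD1A",
    "CD209"
   ],
   "off": [
    "MAFB",
    "KLF4",
    "SELL",
    "CD14",
    "CD206"
   ],
   "exact": {
    "STAT3": 2,
    "PU1": 2,
    "PI3K": 0
   }
  }
 }
}
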