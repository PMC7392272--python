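{
  "notes": "Expansion of slash-named gene-family labels into explicit member symbols, used when the packaged pathway fixtures were built. 'variants' records printed spellings normalized to canonical symbols (e.g. the gamma PKC isoform is PRKCG, and NKF1B is taken as a variant of NFKB1).",
  "expansions": {
    "CSF1/CSF1R": ["CSF1", "CSF1R"],
    "SOS1/2": ["SOS1", "SOS2"],
    "KRAS/NRAS": ["KRAS", "NRAS"],
    "ARAF/RAF1": ["ARAF", "RAF1"],
    "MAP2K1/2": ["MAP2K1", "MAP2K2"],
    "MAPK1/3": ["MAPK1", "MAPK3"],
    "MAPK8/9/10": ["MAPK8", "MAPK9", "MAPK10"],
    "TAB1/2": ["TAB1", "TAB2"],
    "NFKB1/2": ["NFKB1", "NFKB2"],
    "RELA/RELB": ["RELA", "RELB"],
    "LATS1/2": ["LATS1", "LATS2"],
    "YAP1/WWTR1": ["YAP1", "WWTR1"],
    "TGFB": ["TGFB1"],
    "SMAD2/3/4": ["SMAD2", "SMAD3", "SMAD4"],
    "ADCY5/6": ["ADCY5", "ADCY6"],
    "PRKCA/B/G": ["PRKCA", "PRKCB", "PRKCG"],
    "RAPGEF3/4": ["RAPGEF3", "RAPGEF4"],
    "RAP1A/B": ["RAP1A", "RAP1B"],
    "PPP1CA/B/C": ["PPP1CA", "PPP1CB", "PPP1CC"],
    "PI3K": ["PIK3CA", "PIK3CB", "PIK3CD"],
    "AKT1/2/3": ["AKT1", "AKT2", "AKT3"],
    "JAK1/2": ["JAK1", "JAK2"],
    "STAT1/3": ["STAT1", "STAT3"],
    "PTPN11/GRB2": ["PTPN11", "GRB2"],
    "CCND1/2/3": ["CCND1", "CCND2", "CCND3"],
    "NFKB1/RELA": ["NFKB1", "RELA"],
    "CREB": ["CREB1"]
  },
  "variants": {
    "ADYC5/6": "ADCY5/6",
    "ADYCYAPR1R1": "ADCYAP1R1",
    "PRKCA/B/C": "PRKCA/B/G",
    "PTPN11/GRB": "PTPN11/GRB2",
    "NKF1B": "NFKB1",
    "TGFB1": "TGFB"
  }
}
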