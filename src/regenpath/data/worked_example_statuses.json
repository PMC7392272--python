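{
  "notes": "Gene-level calls transcribed from the published flow charts and narrative for the five detailed pathways: 'early' = upregulated in MI vs age-matched control at P7 (red box), 'late' = upregulated at P28 (red text), 'down' = lower in MI than control at P28 (blue text). YAP1/WWTR1 expression was similar between MI and control at both timepoints and is therefore absent from every list.",
  "early": [
    "CSF1", "CSF1R", "CD14", "GRB2", "SOS1", "SOS2", "KRAS", "NRAS",
    "ARAF", "RAF1", "MAP2K1", "MAP2K2", "MAPK1", "MAPK3", "ATF4", "ELK4",
    "MYC", "SRF", "FOS", "MAP3K1", "MAP2K4", "MAPK8", "MAPK9", "MAPK10",
    "JUND", "TAB1", "TAB2", "MAP3K7", "IKBKG", "NFKB1", "NFKB2", "RELA",
    "RELB",
    "NF2", "SAV1", "LATS1", "LATS2", "TGFB1", "SMAD2", "SMAD3", "SMAD4",
    "FGF1", "ITGB2",
    "NPPA", "ADCYAP1R1", "GNAS", "ADCY5", "ADCY6", "PRKCA", "PRKCB",
    "PRKCG", "RAPGEF3", "RAPGEF4", "RAP1A", "RAP1B", "JUN", "AFDN",
    "VAV2", "RAC1", "PAK1", "PIK3CA", "PIK3CB", "PIK3CD", "AKT1", "AKT2",
    "AKT3", "PPP1CA", "PPP1CB", "PPP1CC",
    "JAK1", "JAK2", "STAT1", "STAT3", "PIM1", "CCND1", "CCND2", "CCND3",
    "PTPN11", "HRAS", "MTOR"
  ],
  "late": [
    "CSF1", "CSF1R", "CD14", "TGFB1", "NPPA",
    "ATF4", "FOS", "JUND", "JUN", "MYC", "NFKB1", "NFKB2", "RELA", "RELB",
    "ITGB2", "CCND1", "CCND2", "CCND3", "PIM1", "RAF1", "MTOR"
  ],
  "down": ["CREB1"]
}
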