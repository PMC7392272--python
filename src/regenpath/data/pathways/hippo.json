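{
  "pathway_id": "hippo",
  "name": "Hippo signaling pathway",
  "nodes": [
    {"node_id": "NF2", "label": "NF2 (Merlin)", "role": "initiator", "members": ["NF2"], "annotation": "upstream regulator of the core kinase cassette"},
    {"node_id": "SAV1", "label": "SAV1", "role": "intermediate", "members": ["SAV1"]},
    {"node_id": "LATS1/2", "label": "LATS1/2", "role": "intermediate", "members": ["LATS1", "LATS2"]},
    {"node_id": "YAP1/WWTR1", "label": "YAP1/WWTR1", "role": "effector", "members": ["YAP1", "WWTR1"], "annotation": "transcriptional coactivators; expression unchanged vs age-matched controls at P7 and P28 in the study system"},
    {"node_id": "TGFB", "label": "TGFB", "role": "initiator", "members": ["TGFB1"]},
    {"node_id": "SMAD2/3/4", "label": "SMAD2/3/4", "role": "intermediate", "members": ["SMAD2", "SMAD3", "SMAD4"]},
    {"node_id": "FGF1", "label": "FGF1", "role": "effector", "members": ["FGF1"], "annotation": "proliferative target of the TGFB-SMAD branch"},
    {"node_id": "ITGB2", "label": "ITGB2", "role": "effector", "members": ["ITGB2"]}
  ],
  "edges": [
    ["NF2", "SAV1"],
    ["SAV1", "LATS1/2"],
    ["LATS1/2", "YAP1/WWTR1"],
    ["TGFB", "SMAD2/3/4"],
    ["SMAD2/3/4", "FGF1"],
    ["SMAD2/3/4", "ITGB2"]
  ],
  "subpathways": {
    "core_kinase": ["NF2", "SAV1", "LATS1/2", "YAP1/WWTR1"],
    "tgfb_smad": ["TGFB", "SMAD2/3/4", "FGF1", "ITGB2"]
  }
}
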