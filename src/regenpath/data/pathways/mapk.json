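{
  "pathway_id": "mapk",
  "name": "MAPK signaling pathway",
  "nodes": [
    {"node_id": "CSF1/CSF1R", "label": "CSF1/CSF1R", "role": "initiator", "members": ["CSF1", "CSF1R"], "annotation": "initiating growth-factor/receptor axis"},
    {"node_id": "CD14", "label": "CD14", "role": "initiator", "members": ["CD14"]},
    {"node_id": "GRB2", "label": "GRB2", "role": "intermediate", "members": ["GRB2"]},
    {"node_id": "SOS1/2", "label": "SOS1/2", "role": "intermediate", "members": ["SOS1", "SOS2"]},
    {"node_id": "KRAS/NRAS", "label": "KRAS/NRAS", "role": "intermediate", "members": ["KRAS", "NRAS"]},
    {"node_id": "ARAF/RAF1", "label": "ARAF/RAF1", "role": "intermediate", "members": ["ARAF", "RAF1"]},
    {"node_id": "MAP2K1/2", "label": "MAP2K1/2", "role": "intermediate", "members": ["MAP2K1", "MAP2K2"]},
    {"node_id": "MAPK1/3", "label": "MAPK1/3", "role": "intermediate", "members": ["MAPK1", "MAPK3"]},
    {"node_id": "ATF4", "label": "ATF4", "role": "effector", "members": ["ATF4"]},
    {"node_id": "ELK4", "label": "ELK4", "role": "effector", "members": ["ELK4"]},
    {"node_id": "MYC", "label": "MYC", "role": "effector", "members": ["MYC"]},
    {"node_id": "SRF", "label": "SRF", "role": "effector", "members": ["SRF"]},
    {"node_id": "FOS", "label": "FOS", "role": "effector", "members": ["FOS"]},
    {"node_id": "MAP3K1", "label": "MAP3K1", "role": "intermediate", "members": ["MAP3K1"]},
    {"node_id": "MAP2K4", "label": "MAP2K4", "role": "intermediate", "members": ["MAP2K4"]},
    {"node_id": "MAPK8/9/10", "label": "MAPK8/9/10", "role": "intermediate", "members": ["MAPK8", "MAPK9", "MAPK10"]},
    {"node_id": "JUND", "label": "JUND", "role": "effector", "members": ["JUND"]},
    {"node_id": "TAB1/2", "label": "TAB1/2", "role": "intermediate", "members": ["TAB1", "TAB2"]},
    {"node_id": "MAP3K7", "label": "MAP3K7", "role": "intermediate", "members": ["MAP3K7"]},
    {"node_id": "IKBKG", "label": "IKBKG", "role": "intermediate", "members": ["IKBKG"]},
    {"node_id": "NFKB1/2", "label": "NFKB1/2", "role": "intermediate", "members": ["NFKB1", "NFKB2"]},
    {"node_id": "RELA/RELB", "label": "RELA/RELB", "role": "effector", "members": ["RELA", "RELB"]}
  ],
  "edges": [
    ["CSF1/CSF1R", "GRB2"],
    ["GRB2", "SOS1/2"],
    ["SOS1/2", "KRAS/NRAS"],
    ["KRAS/NRAS", "ARAF/RAF1"],
    ["ARAF/RAF1", "MAP2K1/2"],
    ["MAP2K1/2", "MAPK1/3"],
    ["MAPK1/3", "ATF4"],
    ["MAPK1/3", "ELK4"],
    ["MAPK1/3", "MYC"],
    ["MAPK1/3", "SRF"],
    ["MAPK1/3", "FOS"],
    ["KRAS/NRAS", "MAP3K1"],
    ["MAP3K1", "MAP2K4"],
    ["MAP2K4", "MAPK8/9/10"],
    ["MAPK8/9/10", "FOS"],
    ["MAPK8/9/10", "JUND"],
    ["CD14", "TAB1/2"],
    ["TAB1/2", "MAP3K7"],
    ["MAP3K7", "IKBKG"],
    ["IKBKG", "NFKB1/2"],
    ["NFKB1/2", "RELA/RELB"]
  ],
  "subpathways": {
    "canonical": ["CSF1/CSF1R", "GRB2", "SOS1/2", "KRAS/NRAS", "ARAF/RAF1", "MAP2K1/2", "MAPK1/3", "ATF4", "ELK4", "MYC", "SRF", "FOS"],
    "jnk": ["CSF1/CSF1R", "GRB2", "SOS1/2", "KRAS/NRAS", "MAP3K1", "MAP2K4", "MAPK8/9/10", "FOS", "JUND"],
    "nfkb": ["CD14", "TAB1/2", "MAP3K7", "IKBKG", "NFKB1/2", "RELA/RELB"]
  }
}
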