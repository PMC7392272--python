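{
  "pathway_id": "camp",
  "name": "cAMP signaling pathway",
  "nodes": [
    {"node_id": "NPPA", "label": "NPPA (ANP)", "role": "initiator", "members": ["NPPA"], "annotation": "sole initiating ligand, atrial natriuretic peptide"},
    {"node_id": "ADCYAP1R1", "label": "ADCYAP1R1", "role": "intermediate", "members": ["ADCYAP1R1"], "annotation": "GPCR receptor"},
    {"node_id": "GNAS", "label": "GNAS", "role": "intermediate", "members": ["GNAS"]},
    {"node_id": "ADCY5/6", "label": "ADCY5/6", "role": "intermediate", "members": ["ADCY5", "ADCY6"], "annotation": "adenylyl cyclases"},
    {"node_id": "PRKCA/B/G", "label": "PRKCA/B/G", "role": "intermediate", "members": ["PRKCA", "PRKCB", "PRKCG"]},
    {"node_id": "RAPGEF3/4", "label": "RAPGEF3/4", "role": "intermediate", "members": ["RAPGEF3", "RAPGEF4"], "annotation": "Epac exchange factors"},
    {"node_id": "RAP1A/B", "label": "RAP1A/B", "role": "intermediate", "members": ["RAP1A", "RAP1B"]},
    {"node_id": "MAP2K1/2", "label": "MAP2K1/2", "role": "intermediate", "members": ["MAP2K1", "MAP2K2"]},
    {"node_id": "MAPK1/3", "label": "MAPK1/3", "role": "intermediate", "members": ["MAPK1", "MAPK3"]},
    {"node_id": "JUN", "label": "JUN", "role": "effector", "members": ["JUN"]},
    {"node_id": "FOS", "label": "FOS", "role": "effector", "members": ["FOS"]},
    {"node_id": "AFDN", "label": "AFDN (afadin)", "role": "effector", "members": ["AFDN"], "annotation": "actin cytoskeleton rearrangement, cell-cell adhesion"},
    {"node_id": "VAV2", "label": "VAV2", "role": "intermediate", "members": ["VAV2"]},
    {"node_id": "RAC1", "label": "RAC1", "role": "intermediate", "members": ["RAC1"]},
    {"node_id": "PAK1", "label": "PAK1", "role": "effector", "members": ["PAK1"], "annotation": "cytoskeletal remodeling"},
    {"node_id": "PI3K", "label": "PI3K", "role": "intermediate", "members": ["PIK3CA", "PIK3CB", "PIK3CD"]},
    {"node_id": "AKT1/2/3", "label": "AKT1/2/3", "role": "effector", "members": ["AKT1", "AKT2", "AKT3"], "annotation": "stimulates proliferation"},
    {"node_id": "PPP1CA/B/C", "label": "PPP1CA/B/C", "role": "intermediate", "members": ["PPP1CA", "PPP1CB", "PPP1CC"], "annotation": "CREB-inhibitor phosphatases, promote proliferation"},
    {"node_id": "CREB", "label": "CREB", "role": "effector", "members": ["CREB1"], "annotation": "downregulated at P28 in the study system"}
  ],
  "edges": [
    ["NPPA", "ADCYAP1R1"],
    ["ADCYAP1R1", "GNAS"],
    ["GNAS", "ADCY5/6"],
    ["ADCY5/6", "PRKCA/B/G"],
    ["ADCY5/6", "RAPGEF3/4"],
    ["RAPGEF3/4", "RAP1A/B"],
    ["PRKCA/B/G", "MAP2K1/2"],
    ["RAP1A/B", "MAP2K1/2"],
    ["MAP2K1/2", "MAPK1/3"],
    ["MAPK1/3", "JUN"],
    ["MAPK1/3", "FOS"],
    ["RAP1A/B", "AFDN"],
    ["RAP1A/B", "VAV2"],
    ["VAV2", "RAC1"],
    ["RAC1", "PAK1"],
    ["RAP1A/B", "PI3K"],
    ["PI3K", "AKT1/2/3"],
    ["PRKCA/B/G", "PPP1CA/B/C"],
    ["PPP1CA/B/C", "CREB"]
  ],
  "subpathways": {
    "prkc_mapk": ["NPPA", "ADCYAP1R1", "GNAS", "ADCY5/6", "PRKCA/B/G", "MAP2K1/2", "MAPK1/3", "JUN", "FOS"],
    "rap1": ["NPPA", "ADCYAP1R1", "GNAS", "ADCY5/6", "RAPGEF3/4", "RAP1A/B", "AFDN", "VAV2", "RAC1", "PAK1", "PI3K", "AKT1/2/3"],
    "creb_axis": ["PRKCA/B/G", "PPP1CA/B/C", "CREB"]
  }
}
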