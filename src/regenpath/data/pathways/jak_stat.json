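{
  "pathway_id": "jak_stat",
  "name": "JAK-STAT signaling pathway",
  "nodes": [
    {"node_id": "CSF1/CSF1R", "label": "CSF1/CSF1R", "role": "initiator", "members": ["CSF1", "CSF1R"], "annotation": "cytokine/receptor axis"},
    {"node_id": "JAK1/2", "label": "JAK1/2", "role": "intermediate", "members": ["JAK1", "JAK2"]},
    {"node_id": "STAT1/3", "label": "STAT1/3", "role": "intermediate", "members": ["STAT1", "STAT3"]},
    {"node_id": "PIM1", "label": "PIM1", "role": "effector", "members": ["PIM1"], "annotation": "anti-apoptotic branch"},
    {"node_id": "MYC", "label": "MYC", "role": "intermediate", "members": ["MYC"]},
    {"node_id": "CCND1/2/3", "label": "CCND1/2/3", "role": "effector", "members": ["CCND1", "CCND2", "CCND3"], "annotation": "cell-cycle progression"},
    {"node_id": "PTPN11/GRB2", "label": "PTPN11/GRB2", "role": "intermediate", "members": ["PTPN11", "GRB2"]},
    {"node_id": "SOS1/2", "label": "SOS1/2", "role": "intermediate", "members": ["SOS1", "SOS2"]},
    {"node_id": "HRAS", "label": "HRAS", "role": "intermediate", "members": ["HRAS"]},
    {"node_id": "RAF1", "label": "RAF1", "role": "effector", "members": ["RAF1"], "annotation": "proliferation/differentiation branch"},
    {"node_id": "PI3K", "label": "PI3K", "role": "intermediate", "members": ["PIK3CA", "PIK3CB", "PIK3CD"]},
    {"node_id": "AKT1/2/3", "label": "AKT1/2/3", "role": "intermediate", "members": ["AKT1", "AKT2", "AKT3"]},
    {"node_id": "MTOR", "label": "MTOR", "role": "effector", "members": ["MTOR"], "annotation": "cell cycle and survival"}
  ],
  "edges": [
    ["CSF1/CSF1R", "JAK1/2"],
    ["JAK1/2", "STAT1/3"],
    ["STAT1/3", "PIM1"],
    ["STAT1/3", "MYC"],
    ["MYC", "CCND1/2/3"],
    ["CSF1/CSF1R", "PTPN11/GRB2"],
    ["PTPN11/GRB2", "SOS1/2"],
    ["SOS1/2", "HRAS"],
    ["HRAS", "RAF1"],
    ["JAK1/2", "PI3K"],
    ["PI3K", "AKT1/2/3"],
    ["AKT1/2/3", "MTOR"]
  ],
  "subpathways": {
    "pim1": ["CSF1/CSF1R", "JAK1/2", "STAT1/3", "PIM1"],
    "myc_ccnd": ["CSF1/CSF1R", "JAK1/2", "STAT1/3", "MYC", "CCND1/2/3"],
    "ras_raf": ["CSF1/CSF1R", "PTPN11/GRB2", "SOS1/2", "HRAS", "RAF1"],
    "pi3k_mtor": ["CSF1/CSF1R", "JAK1/2", "PI3K", "AKT1/2/3", "MTOR"]
  }
}
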