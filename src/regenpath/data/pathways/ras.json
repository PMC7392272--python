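{
  "pathway_id": "ras",
  "name": "Ras signaling pathway",
  "nodes": [
    {"node_id": "CSF1/CSF1R", "label": "CSF1/CSF1R", "role": "initiator", "members": ["CSF1", "CSF1R"]},
    {"node_id": "AFDN", "label": "AFDN (afadin)", "role": "effector", "members": ["AFDN"], "annotation": "intercellular junction formation"},
    {"node_id": "PI3K", "label": "PI3K", "role": "intermediate", "members": ["PIK3CA", "PIK3CB", "PIK3CD"]},
    {"node_id": "AKT1/2/3", "label": "AKT1/2/3", "role": "intermediate", "members": ["AKT1", "AKT2", "AKT3"]},
    {"node_id": "IKBKG", "label": "IKBKG", "role": "intermediate", "members": ["IKBKG"]},
    {"node_id": "NFKB1/RELA", "label": "NFKB1/RELA", "role": "effector", "members": ["NFKB1", "RELA"], "annotation": "cell-cycle progression, growth, migration, survival"}
  ],
  "edges": [
    ["CSF1/CSF1R", "AFDN"],
    ["CSF1/CSF1R", "PI3K"],
    ["PI3K", "AKT1/2/3"],
    ["AKT1/2/3", "IKBKG"],
    ["IKBKG", "NFKB1/RELA"]
  ],
  "subpathways": {
    "junctions": ["CSF1/CSF1R", "AFDN"],
    "nfkb": ["CSF1/CSF1R", "PI3K", "AKT1/2/3", "IKBKG", "NFKB1/RELA"]
  }
}
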