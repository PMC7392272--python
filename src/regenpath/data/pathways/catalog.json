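{
  "notes": "Twenty candidate cell-cycle / cell-fate signaling pathways screened for the neonatal infarction model. Five carry detailed initiator-to-effector graphs transcribed from the study's flow charts; the other fifteen have no node lists and are reported as 'not called'. The source text gives the candidate count variously as 11 or 20; this catalog follows the enumerated 20-item list.",
  "entries": [
    {"pathway_id": "mapk", "name": "MAPK signaling pathway", "graph_file": "mapk.json"},
    {"pathway_id": "hippo", "name": "Hippo signaling pathway", "graph_file": "hippo.json"},
    {"pathway_id": "ras", "name": "Ras signaling pathway", "graph_file": "ras.json"},
    {"pathway_id": "vegf", "name": "VEGF signaling pathway"},
    {"pathway_id": "wnt", "name": "Wnt signaling pathway"},
    {"pathway_id": "rap1", "name": "Rap1 signaling pathway"},
    {"pathway_id": "hedgehog", "name": "Hedgehog signaling pathway"},
    {"pathway_id": "jak_stat", "name": "JAK-STAT signaling pathway", "graph_file": "jak_stat.json"},
    {"pathway_id": "camp", "name": "cAMP signaling pathway", "graph_file": "camp.json"},
    {"pathway_id": "erbb", "name": "ErbB signaling pathway"},
    {"pathway_id": "cgmp_pkg", "name": "cGMP-PKG signaling pathway"},
    {"pathway_id": "apelin", "name": "Apelin signaling pathway"},
    {"pathway_id": "nfkb", "name": "NF-kappa B signaling pathway"},
    {"pathway_id": "tnf", "name": "TNF signaling pathway"},
    {"pathway_id": "hif1", "name": "HIF-1 signaling pathway"},
    {"pathway_id": "foxo", "name": "FoxO signaling pathway"},
    {"pathway_id": "sphingolipid", "name": "Sphingolipid signaling pathway"},
    {"pathway_id": "phospholipase_d", "name": "Phospholipase D signaling pathway"},
    {"pathway_id": "mtor", "name": "mTOR signaling pathway"},
    {"pathway_id": "ampk", "name": "AMPK signaling pathway"}
  ]
}
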