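{
  "name": "jdm_biopsy_score_tool",
  "version": "1.0",
  "vas": {"min": 0.0, "max": 10.0},
  "items": [
    {"id": "cd3_endomysial", "domain": "inflammatory", "levels": [0, 1, 2], "label": "CD3+ endomysial infiltration"},
    {"id": "cd3_perimysial", "domain": "inflammatory", "levels": [0, 1, 2], "label": "CD3+ perimysial infiltration"},
    {"id": "cd3_perivascular", "domain": "inflammatory", "levels": [0, 1, 2], "label": "CD3+ perivascular infiltration"},
    {"id": "cd68_endomysial", "domain": "inflammatory", "levels": [0, 1, 2], "label": "CD68+ endomysial infiltration"},
    {"id": "cd68_perimysial", "domain": "inflammatory", "levels": [0, 1, 2], "label": "CD68+ perimysial infiltration"},
    {"id": "cd68_perivascular", "domain": "inflammatory", "levels": [0, 1, 2], "label": "CD68+ perivascular infiltration"},
    {"id": "capillary_dropout", "domain": "vascular", "levels": [0, 1, 2], "label": "Capillary dropout"},
    {"id": "arterial_abnormality", "domain": "vascular", "levels": [0, 1, 2], "label": "Arterial abnormality"},
    {"id": "infarction", "domain": "vascular", "levels": [0, 1], "label": "Infarction"},
    {"id": "mhc_class_i", "domain": "muscle_fibre", "levels": [0, 1, 2], "label": "MHC class I overexpression"},
    {"id": "perifascicular_atrophy", "domain": "muscle_fibre", "levels": [0, 1, 2], "label": "Perifascicular atrophy"},
    {"id": "neonatal_myosin", "domain": "muscle_fibre", "levels": [0, 1], "label": "Neonatal myosin expression"},
    {"id": "fibre_atrophy_non_perifascicular", "domain": "muscle_fibre", "levels": [0, 1, 2], "label": "Fibre atrophy: non-perifascicular"},
    {"id": "regen_perifascicular", "domain": "muscle_fibre", "levels": [0, 1, 2], "label": "Regeneration/degeneration/necrosis: perifascicular"},
    {"id": "regen_non_perifascicular", "domain": "muscle_fibre", "levels": [0, 1, 2], "label": "Regeneration/degeneration/necrosis: non-perifascicular"},
    {"id": "internal_myonuclei", "domain": "muscle_fibre", "levels": [0, 1, 2], "label": "Internal myonuclei"},
    {"id": "endomysial_fibrosis", "domain": "connective_tissue", "levels": [0, 1, 2], "label": "Any endomysial fibrosis"},
    {"id": "perimysial_fibrosis", "domain": "connective_tissue", "levels": [0, 1, 2], "label": "Any perimysial fibrosis"}
  ]
}
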