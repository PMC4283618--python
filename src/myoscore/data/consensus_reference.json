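{
  "comment": "Published consensus-score comparison for the six informative items and the modified domain totals, quadriceps (n=33) vs biceps (n=22). Contingency counts are rows (quadriceps, biceps) by ascending tool score.",
  "informative_items": [
    "cd3_endomysial",
    "cd3_perimysial",
    "cd68_endomysial",
    "perifascicular_atrophy",
    "neonatal_myosin",
    "regen_perifascicular"
  ],
  "contingency": {
    "cd3_endomysial": {"levels": [0, 1, 2], "counts": [[11, 14, 8], [11, 9, 2]], "p_printed": 0.27},
    "cd3_perimysial": {"levels": [0, 1, 2], "counts": [[11, 12, 10], [12, 7, 3]], "p_printed": 0.22},
    "cd68_endomysial": {"levels": [0, 1, 2], "counts": [[2, 8, 23], [3, 5, 14]], "p_printed": 0.63},
    "perifascicular_atrophy": {"levels": [0, 1, 2], "counts": [[22, 0, 11], [6, 1, 15]], "p_printed": 0.01},
    "neonatal_myosin": {"levels": [0, 1], "counts": [[9, 24], [8, 14]], "p_printed": 0.48},
    "regen_perifascicular": {"levels": [0, 1, 2], "counts": [[20, 2, 11], [6, 1, 15]], "p_printed": 0.04}
  },
  "modified_totals": {
    "inflammatory": {"possible_range": [0, 6], "quadriceps": {"median": 4.0, "iqr": [1.5, 5.0]}, "biceps": {"median": 2.5, "iqr": [1.0, 4.0]}, "p_printed": 0.15},
    "muscle_fibre": {"possible_range": [0, 5], "quadriceps": {"median": 2.0, "iqr": [0.0, 4.0]}, "biceps": {"median": 5.0, "iqr": [1.0, 5.0]}, "p_printed": 0.01}
  },
  "vas": {"range": [0, 10], "quadriceps": {"median": 3.3, "iqr": [1.1, 5.9]}, "biceps": {"median": 6.1, "iqr": [2.2, 7.5]}, "p_printed": 0.023},
  "mmt_associations": {
    "comment": "Spearman rank correlations (r) of consensus scores with manual muscle testing for the combined cohort; p from the test of independence.",
    "rows": [
      {"row_id": "cd3_endomysial", "knee_r": -0.40, "knee_p": "0.006", "elbow_r": -0.44, "elbow_p": "0.003"},
      {"row_id": "cd3_perimysial", "knee_r": -0.40, "knee_p": "0.007", "elbow_r": -0.41, "elbow_p": "0.006"},
      {"row_id": "cd68_endomysial", "knee_r": -0.53, "knee_p": "0.002", "elbow_r": -0.62, "elbow_p": "<0.001"},
      {"row_id": "inflammatory_domain_total_modified", "knee_r": -0.56, "knee_p": "0.001", "elbow_r": -0.59, "elbow_p": "<0.0001"},
      {"row_id": "perifascicular_atrophy", "knee_r": -0.30, "knee_p": "0.040", "elbow_r": -0.40, "elbow_p": "0.006"},
      {"row_id": "neonatal_myosin", "knee_r": -0.57, "knee_p": "0.001", "elbow_r": -0.57, "elbow_p": "<0.001"},
      {"row_id": "regen_perifascicular", "knee_r": -0.38, "knee_p": "0.009", "elbow_r": -0.53, "elbow_p": "0.002"},
      {"row_id": "muscle_fibre_domain_total_modified", "knee_r": -0.45, "knee_p": "0.002", "elbow_r": -0.60, "elbow_p": "<0.0001"},
      {"row_id": "vas", "knee_r": -0.45, "knee_p": "0.002", "elbow_r": -0.62, "elbow_p": "<0.0001"}
    ]
  }
}
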