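{
  "comment": "Group-level summaries of the published JDM validation cohort: 55 cases, quadriceps biopsies from the UK cohort, biceps from the Brazil cohort. Counts in 2xK tables are rows (quadriceps, biceps) by ordered category.",
  "groups": {
    "quadriceps": {"n": 33, "cohort": "UK"},
    "biceps": {"n": 22, "cohort": "Brazil"}
  },
  "demographics": {
    "age_at_biopsy_years": {"quadriceps": {"median": 6.2, "iqr": [3.3, 10.0]}, "biceps": {"median": 7.5, "iqr": [6.0, 9.3]}, "p": 0.37},
    "age_at_onset_years": {"quadriceps": {"median": 5.7, "iqr": [3.3, 9.5]}, "biceps": {"median": 7.1, "iqr": [5.7, 9.1]}, "p": 0.31},
    "months_to_biopsy": {"quadriceps": {"median": 3.0, "iqr": [2.0, 6.5]}, "biceps": {"median": 2.5, "iqr": [1.9, 5.4]}, "p": 0.17}
  },
  "binary_tables": {
    "gender_female": {"counts": [[21, 12], [17, 5]], "p": 0.36},
    "calcinosis": {"counts": [[0, 33], [6, 16]], "p": 0.002},
    "skin_ulceration": {"counts": [[4, 28], [3, 19]], "p": 0.903},
    "lung": {"counts": [[8, 24], [5, 17]], "p": 0.848},
    "cardiac": {"counts": [[0, 32], [2, 20]], "p": 0.161},
    "gi": {"counts": [[10, 22], [9, 13]], "p": 0.465}
  },
  "mmt_tables": {
    "mmt_knee_extensor": {"levels": [2, 3, 4, 5], "counts": [[5, 8, 7, 4], [4, 8, 10, 0]], "p": 0.238},
    "mmt_elbow_flexion": {"levels": [2, 3, 4, 5], "counts": [[2, 10, 6, 5], [4, 8, 9, 1]], "p": 0.273}
  },
  "uk_only": {
    "cmas": {"median": 23.5, "iqr": [13.3, 36.8], "range": [0, 53]},
    "pga": {"median": 5.9, "iqr": [3.5, 7.2], "range": [0.0, 10.0]}
  }
}
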