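row_id,muscle,composite,icc,icc_lo,icc_hi,alpha,alpha_lo,alpha_hi,bold,degenerate
inflammatory_domain_total,quadriceps,1,0.81,0.61,0.93,0.38,0.19,0.74,1,0
inflammatory_domain_total,biceps,1,0.80,0.62,0.93,0.34,0.16,0.68,1,0
cd3_endomysial,quadriceps,0,0.72,0.53,0.89,0.15,0.0,0.39,1,0
cd3_endomysial,biceps,0,0.74,0.56,0.90,0.26,0.08,0.54,1,0
cd3_perimysial,quadriceps,0,0.61,0.39,0.83,0.31,0.05,0.67,1,0
cd3_perimysial,biceps,0,0.75,0.57,0.91,0.20,0.0,0.44,1,0
cd3_perivascular,quadriceps,0,0.58,0.37,0.82,0.41,0.14,0.84,0,0
cd3_perivascular,biceps,0,0.58,0.37,0.82,0.44,0.17,0.90,0,0
cd68_endomysial,quadriceps,0,0.66,0.45,0.86,0.40,0.17,0.82,1,0
cd68_endomysial,biceps,0,0.62,0.41,0.84,0.22,0.0,0.53,1,0
cd68_perimysial,quadriceps,0,0.48,0.27,0.76,0.59,0.24,1.2,0,0
cd68_perimysial,biceps,0,0.79,0.63,0.93,0.18,0.0,0.40,1,0
cd68_perivascular,quadriceps,0,0.40,0.20,0.70,0.83,0.37,1.65,0,0
cd68_perivascular,biceps,0,0.33,0.15,0.63,0.97,0.43,0.93,0,0
vascular_domain_total,quadriceps,1,0.48,0.27,0.76,0.57,0.23,1.2,0,0
vascular_domain_total,biceps,1,0.49,0.28,0.76,0.54,0.21,1.10,0,0
capillary_dropout,quadriceps,0,0.39,0.20,0.68,0.73,0.29,1.47,0,0
capillary_dropout,biceps,0,0.26,0.11,0.55,0.95,0.34,2.0,0,0
arterial_abnormality,quadriceps,0,0.40,0.21,0.70,0.56,0.18,1.18,0,0
arterial_abnormality,biceps,0,0.42,0.23,0.71,0.52,0.15,1.09,0,0
infarction,quadriceps,0,0.0,0.0,0.16,0.0,0.0,0.0,1,1
infarction,biceps,0,0.42,0.22,0.71,0.34,0.0,0.80,1,0
muscle_fibre_domain_total,quadriceps,1,0.80,0.63,0.93,0.25,0.10,0.52,1,0
muscle_fibre_domain_total,biceps,1,0.86,0.71,0.95,0.26,0.12,0.52,1,0
mhc_class_i,quadriceps,0,0.31,0.14,0.62,0.28,0.0,0.82,1,0
mhc_class_i,biceps,0,0.0,0.0,0.14,0.0,0.0,0.0,1,1
perifascicular_atrophy,quadriceps,0,0.63,0.43,0.85,0.28,0.0,0.61,1,0
perifascicular_atrophy,biceps,0,0.76,0.58,0.91,0.29,0.11,0.59,1,0
neonatal_myosin,quadriceps,0,0.83,0.68,0.94,0.0,0.0,0.20,1,0
neonatal_myosin,biceps,0,0.88,0.76,0.96,0.06,0.0,0.20,1,0
fibre_atrophy_non_perifascicular,quadriceps,0,0.28,0.13,0.59,0.83,0.29,1.72,0,0
fibre_atrophy_non_perifascicular,biceps,0,0.32,0.15,0.62,0.76,0.26,1.56,0,0
regen_perifascicular,quadriceps,0,0.58,0.36,0.82,0.39,0.12,0.81,1,0
regen_perifascicular,biceps,0,0.84,0.70,0.94,0.18,0.05,0.30,1,0
regen_non_perifascicular,quadriceps,0,0.51,0.30,0.78,0.38,0.05,0.81,1,0
regen_non_perifascicular,biceps,0,0.60,0.38,0.83,0.50,0.22,1.0,0,0
internal_myonuclei,quadriceps,0,0.63,0.42,0.85,0.33,0.09,0.69,1,0
internal_myonuclei,biceps,0,0.32,0.15,0.63,0.63,0.16,1.34,0,0
connective_tissue_domain_total,quadriceps,1,0.34,0.16,0.64,0.74,0.27,1.52,0,0
connective_tissue_domain_total,biceps,1,0.41,0.21,0.70,0.62,0.23,1.28,0,0
endomysial_fibrosis,quadriceps,0,0.35,0.17,0.65,0.66,0.22,1.38,0,0
endomysial_fibrosis,biceps,0,0.32,0.15,0.63,0.60,0.11,1.39,0,0
perimysial_fibrosis,quadriceps,0,0.19,0.07,0.47,1.03,0.26,2.17,0,0
perimysial_fibrosis,biceps,0,0.36,0.18,0.66,0.70,0.26,1.44,0,0
vas,quadriceps,1,0.77,0.60,0.91,0.20,0.03,0.44,1,0
vas,biceps,1,0.87,0.74,0.96,0.19,0.08,0.40,1,0
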