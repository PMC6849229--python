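condition,community_mean,community_mean_lo,community_mean_hi,trial_mean,trial_mean_lo,trial_mean_hi,ratio,ratio_lo,ratio_hi,community_p_ge2,community_p_ge2_lo,community_p_ge2_hi,trial_p_ge2,trial_p_ge2_lo,trial_p_ge2_hi
pulmonary_fibrosis,3.61,3.49,3.75,2.17,1.03,3.92,1.87,0.90,3.49,0.88,0.86,0.91,0.61,0.28,0.90
dementia,3.44,3.38,3.49,1.56,1.10,2.18,2.27,1.58,3.11,0.82,0.81,0.83,0.46,0.30,0.64
pulmonary_hypertension,3.27,3.01,3.53,2.09,1.93,2.26,1.57,1.39,1.75,0.80,0.75,0.84,0.58,0.53,0.63
osteoporosis,3.01,2.99,3.03,2.07,1.43,2.95,1.50,1.02,2.10,0.79,0.79,0.80,0.60,0.42,0.79
parkinsons_disease,3.00,2.90,3.10,1.36,0.78,2.18,2.37,1.37,3.86,0.75,0.73,0.77,0.39,0.18,0.64
type_2_diabetes,2.95,2.94,2.96,0.79,0.43,1.32,4.06,2.23,6.83,0.78,0.78,0.78,0.27,0.19,0.36
restless_legs_syndrome,2.85,2.81,2.89,1.68,0.83,2.98,1.89,0.96,3.42,0.74,0.73,0.75,0.48,0.20,0.80
copd,2.76,2.75,2.78,1.46,1.00,2.07,1.96,1.33,2.78,0.75,0.74,0.75,0.43,0.26,0.61
thromboembolism,2.52,2.48,2.56,1.33,0.80,2.00,2.00,1.24,3.13,0.68,0.67,0.70,0.38,0.19,0.59
systemic_lupus_erythematosus,2.51,2.35,2.68,2.30,1.08,4.12,1.22,0.60,2.32,0.69,0.65,0.73,0.63,0.29,0.92
erectile_dysfunction,2.44,2.43,2.45,1.08,0.99,1.17,2.27,2.08,2.47,0.69,0.69,0.69,0.32,0.29,0.36
benign_prostatic_hyperplasia,2.37,2.34,2.40,1.11,0.70,1.69,2.24,1.40,3.36,0.66,0.66,0.67,0.30,0.16,0.50
migraine,2.33,2.31,2.35,0.98,0.63,1.42,2.50,1.65,3.73,0.70,0.69,0.71,0.26,0.13,0.42
atrial_fibrillation,2.22,2.20,2.23,1.08,1.07,1.10,2.05,2.01,2.08,0.63,0.63,0.64,0.29,0.29,0.30
osteoarthritis,2.14,2.13,2.15,1.79,1.72,1.86,1.20,1.15,1.24,0.61,0.61,0.61,0.54,0.51,0.56
rheumatoid_arthritis,2.07,2.03,2.10,1.14,0.87,1.51,1.84,1.37,2.39,0.59,0.58,0.60,0.32,0.22,0.44
hypertension,1.91,1.90,1.91,0.50,0.36,0.69,3.88,2.76,5.28,0.54,0.54,0.54,0.09,0.05,0.15
psoriatic_arthropathy,1.84,1.78,1.89,0.67,0.38,1.09,2.96,1.71,4.88,0.51,0.50,0.53,0.15,0.06,0.30
asthma,1.81,1.81,1.82,0.58,0.35,0.92,3.32,1.97,5.24,0.51,0.50,0.51,0.12,0.05,0.23
inflammatory_bowel_disease,1.55,1.52,1.58,0.92,0.68,1.18,1.73,1.32,2.28,0.44,0.43,0.45,0.23,0.15,0.33
axial_spondyloarthritis,1.42,1.34,1.50,0.88,0.43,1.58,1.79,0.90,3.31,0.40,0.37,0.43,0.22,0.07,0.47
psoriasis,1.35,1.34,1.37,0.69,0.48,0.99,2.02,1.36,2.80,0.39,0.39,0.40,0.15,0.08,0.26
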