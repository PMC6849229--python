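index_condition,suppressed_comorbidity
type_2_diabetes,diabetes_mellitus
asthma,asthma_copd
copd,asthma_copd
hypertension,cardiovascular_disease
atrial_fibrillation,cardiovascular_disease
atrial_fibrillation,thromboembolic_disease
thromboembolism,thromboembolic_disease
pulmonary_fibrosis,inflammatory_conditions
pulmonary_hypertension,cardiovascular_disease
axial_spondyloarthritis,arthritis
axial_spondyloarthritis,inflammatory_conditions
inflammatory_bowel_disease,inflammatory_conditions
psoriasis,inflammatory_conditions
psoriatic_arthropathy,arthritis
psoriatic_arthropathy,inflammatory_conditions
rheumatoid_arthritis,arthritis
rheumatoid_arthritis,inflammatory_conditions
systemic_lupus_erythematosus,inflammatory_conditions
osteoarthritis,arthritis
osteoporosis,osteoporosis
dementia,dementia
migraine,migraine
parkinsons_disease,parkinsonism
restless_legs_syndrome,parkinsonism
benign_prostatic_hyperplasia,benign_prostatic_hyperplasia
erectile_dysfunction,erectile_dysfunction
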