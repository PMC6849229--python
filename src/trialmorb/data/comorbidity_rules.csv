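comorbidity,atc_prefix,action
cardiovascular_disease,C01,include
cardiovascular_disease,C02,include
cardiovascular_disease,C03,include
cardiovascular_disease,C07,include
cardiovascular_disease,C08,include
cardiovascular_disease,C09,include
cardiovascular_disease,C10,include
chronic_pain,N02A,include
chronic_pain,N02B,include
arthritis,M01A,include
affective_disorders,N06A,include
affective_disorders,N06AA09,exclude
acid_related_disorders,A02B,include
asthma_copd,R03,include
diabetes_mellitus,A10,include
osteoporosis,M05B,include
thyroid_disease,H03,include
thromboembolic_disease,B01A,include
inflammatory_conditions,L04A,include
benign_prostatic_hyperplasia,G04C,include
gout,M04A,include
glaucoma,S01E,include
urinary_incontinence,G04BD,include
erectile_dysfunction,G04BE,include
psychotic_disorders,N05A,include
epilepsy,N03A,include
migraine,N02C,include
parkinsonism,N04,include
dementia,N06D,include
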