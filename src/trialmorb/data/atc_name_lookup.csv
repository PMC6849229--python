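drug_name,route,atc_code
omeprazole,oral,A02BC01
metformin,oral,A10BA02
insulin glargine,subcutaneous,A10AE04
salbutamol,inhaled,R03AC02
budesonide,inhaled,R03BA02
atorvastatin,oral,C10AA05
amlodipine,oral,C08CA01
ramipril,oral,C09AA05
bisoprolol,oral,C07AB07
sertraline,oral,N06AB06
citalopram,oral,N06AB04
paracetamol,oral,N02BE01
morphine,oral,N02AA01
ibuprofen,oral,M01AE01
naproxen,oral,M01AE02
alendronic acid,oral,M05BA04
levothyroxine,oral,H03AA01
warfarin,oral,B01AA03
apixaban,oral,B01AF02
methotrexate,oral,L04AX03
azathioprine,oral,L04AX01
tamsulosin,oral,G04CA02
allopurinol,oral,M04AA01
latanoprost,ocular,S01EE01
oxybutynin,oral,G04BD04
sildenafil,oral,G04BE03
risperidone,oral,N05AX08
quetiapine,oral,N05AH04
valproate,oral,N03AG01
lamotrigine,oral,N03AX09
sumatriptan,oral,N02CC01
levodopa,oral,N04BA01
ropinirole,oral,N04BC04
donepezil,oral,N06DA02
memantine,oral,N06DX01
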