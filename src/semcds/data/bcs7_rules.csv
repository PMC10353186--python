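# AJCC 7th-edition anatomic stage grouping for breast cancer (19 criteria).
# Biomarker columns are unused ("*") in this edition.
rule_id,edition,t,n,m,grade,her2,er,pr,stage
bcs7-01,bcs7,Tis,N0,M0,*,*,*,*,0
bcs7-02,bcs7,T1,N0,M0,*,*,*,*,IA
bcs7-03,bcs7,T0,N1mi,M0,*,*,*,*,IB
bcs7-04,bcs7,T1,N1mi,M0,*,*,*,*,IB
bcs7-05,bcs7,T0,N1,M0,*,*,*,*,IIA
bcs7-06,bcs7,T1,N1,M0,*,*,*,*,IIA
bcs7-07,bcs7,T2,N0,M0,*,*,*,*,IIA
bcs7-08,bcs7,T2,N1,M0,*,*,*,*,IIB
bcs7-09,bcs7,T3,N0,M0,*,*,*,*,IIB
bcs7-10,bcs7,T0,N2,M0,*,*,*,*,IIIA
bcs7-11,bcs7,T1,N2,M0,*,*,*,*,IIIA
bcs7-12,bcs7,T2,N2,M0,*,*,*,*,IIIA
bcs7-13,bcs7,T3,N1,M0,*,*,*,*,IIIA
bcs7-14,bcs7,T3,N2,M0,*,*,*,*,IIIA
bcs7-15,bcs7,T4,N0,M0,*,*,*,*,IIIB
bcs7-16,bcs7,T4,N1,M0,*,*,*,*,IIIB
bcs7-17,bcs7,T4,N2,M0,*,*,*,*,IIIB
bcs7-18,bcs7,*,N3,M0,*,*,*,*,IIIC
bcs7-19,bcs7,*,*,M1,*,*,*,*,IV
# Stage-level care annotations (tests/treatments are ";"-separated lists).
stage,recommended_tests,treatment_options,comment
0,Diagnostic mammography;Breast ultrasound,Breast-conserving surgery;Radiation therapy,Carcinoma in situ without invasion
IA,Diagnostic mammography;Sentinel lymph node biopsy,Breast-conserving surgery;Radiation therapy;Endocrine therapy,Small invasive tumor without nodal spread
IB,Diagnostic mammography;Sentinel lymph node biopsy,Breast-conserving surgery;Radiation therapy;Endocrine therapy,Micrometastatic nodal involvement
IIA,Breast MRI;Sentinel lymph node biopsy,Surgery;Radiation therapy;Adjuvant chemotherapy,Early-stage disease with limited nodal spread
IIB,Breast MRI;Axillary staging,Surgery;Radiation therapy;Adjuvant chemotherapy,Larger tumor or limited nodal spread
IIIA,Breast MRI;CT chest/abdomen;Bone scan,Neoadjuvant chemotherapy;Surgery;Radiation therapy,Locally advanced disease
IIIB,Breast MRI;CT chest/abdomen;Bone scan,Neoadjuvant chemotherapy;Surgery;Radiation therapy,Chest-wall or skin involvement
IIIC,CT chest/abdomen;Bone scan;PET-CT,Neoadjuvant chemotherapy;Surgery;Radiation therapy,Extensive regional nodal involvement
IV,CT chest/abdomen;Bone scan;PET-CT;Biopsy of metastatic site,Systemic therapy;Palliative radiation;Clinical trial enrollment,Distant metastatic disease
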