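# AJCC 8th-edition prognostic stage grouping for breast cancer —
# ILLUSTRATIVE SUBSET (30 of the 407 published criteria).
# The full prognostic table is licensed by the AJCC and must be supplied by
# the user as a rules CSV in this dialect; the engine validates and applies
# it identically.  This subset refines the T1/T2 node-negative and T1/N1
# strata by grade and HER2/ER/PR receptor status (favorable biology
# down-stages, unfavorable biology up-stages) and keeps the anatomic rows
# elsewhere, including the universal M1 -> IV row.
rule_id,edition,t,n,m,grade,her2,er,pr,stage
bcs8-01,bcs8-subset,Tis,N0,M0,*,*,*,*,0
bcs8-02,bcs8-subset,T1,N0,M0,G1,*,*,*,IA
bcs8-03,bcs8-subset,T1,N0,M0,G2,*,*,*,IA
bcs8-04,bcs8-subset,T1,N0,M0,G3,positive,*,*,IA
bcs8-05,bcs8-subset,T1,N0,M0,G3,negative,positive,*,IA
bcs8-06,bcs8-subset,T1,N0,M0,G3,negative,negative,*,IB
bcs8-07,bcs8-subset,T2,N0,M0,G1,*,positive,*,IB
bcs8-08,bcs8-subset,T2,N0,M0,G1,*,negative,*,IIA
bcs8-09,bcs8-subset,T2,N0,M0,G2,*,*,*,IIA
bcs8-10,bcs8-subset,T2,N0,M0,G3,*,*,*,IIB
bcs8-11,bcs8-subset,T0,N1mi,M0,*,*,*,*,IB
bcs8-12,bcs8-subset,T1,N1mi,M0,*,*,*,*,IB
bcs8-13,bcs8-subset,T0,N1,M0,*,*,*,*,IIA
bcs8-14,bcs8-subset,T1,N1,M0,G1,*,positive,positive,IB
bcs8-15,bcs8-subset,T1,N1,M0,G1,*,positive,negative,IIA
bcs8-16,bcs8-subset,T1,N1,M0,G1,*,negative,*,IIA
bcs8-17,bcs8-subset,T1,N1,M0,G2,*,*,*,IIA
bcs8-18,bcs8-subset,T1,N1,M0,G3,*,*,*,IIB
bcs8-19,bcs8-subset,T2,N1,M0,*,*,*,*,IIB
bcs8-20,bcs8-subset,T3,N0,M0,*,*,*,*,IIB
bcs8-21,bcs8-subset,T0,N2,M0,*,*,*,*,IIIA
bcs8-22,bcs8-subset,T1,N2,M0,*,*,*,*,IIIA
bcs8-23,bcs8-subset,T2,N2,M0,*,*,*,*,IIIA
bcs8-24,bcs8-subset,T3,N1,M0,*,*,*,*,IIIA
bcs8-25,bcs8-subset,T3,N2,M0,*,*,*,*,IIIA
bcs8-26,bcs8-subset,T4,N0,M0,*,*,*,*,IIIB
bcs8-27,bcs8-subset,T4,N1,M0,*,*,*,*,IIIB
bcs8-28,bcs8-subset,T4,N2,M0,*,*,*,*,IIIB
bcs8-29,bcs8-subset,*,N3,M0,*,*,*,*,IIIC
bcs8-30,bcs8-subset,*,*,M1,*,*,*,*,IV
stage,recommended_tests,treatment_options,comment
0,Diagnostic mammography;Breast ultrasound,Breast-conserving surgery;Radiation therapy,Carcinoma in situ without invasion
IA,Diagnostic mammography;Sentinel lymph node biopsy;Receptor panel (HER2/ER/PR),Breast-conserving surgery;Radiation therapy;Endocrine therapy,Favorable prognostic group
IB,Diagnostic mammography;Sentinel lymph node biopsy;Receptor panel (HER2/ER/PR),Surgery;Radiation therapy;Endocrine therapy,Intermediate prognostic group
IIA,Breast MRI;Sentinel lymph node biopsy;Receptor panel (HER2/ER/PR),Surgery;Radiation therapy;Adjuvant chemotherapy,Early-stage prognostic group
IIB,Breast MRI;Axillary staging;Receptor panel (HER2/ER/PR),Surgery;Radiation therapy;Adjuvant chemotherapy;HER2-targeted therapy,Unfavorable biology or larger tumor
IIIA,Breast MRI;CT chest/abdomen;Bone scan,Neoadjuvant chemotherapy;Surgery;Radiation therapy,Locally advanced disease
IIIB,Breast MRI;CT chest/abdomen;Bone scan,Neoadjuvant chemotherapy;Surgery;Radiation therapy,Chest-wall or skin involvement
IIIC,CT chest/abdomen;Bone scan;PET-CT,Neoadjuvant chemotherapy;Surgery;Radiation therapy,Extensive regional nodal involvement
IV,CT chest/abdomen;Bone scan;PET-CT;Biopsy of metastatic site,Systemic therapy;Palliative radiation;Clinical trial enrollment,Distant metastatic disease
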