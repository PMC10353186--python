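surface,code,preferred_label,category
age,age,Age,demographic
sex,sex,Sex,demographic
gender,sex,Sex,demographic
female,female,Female,demographic
male,male,Male,demographic
race,race,Race,demographic
ethnicity,race,Race,demographic
race ethnicity,race,Race,demographic
white,white,White,demographic
black,african_american,African American,demographic
african american,african_american,African American,demographic
black or african american,african_american,African American,demographic
hispanic,hispanic,Hispanic or Latino,demographic
hispanic or latino,hispanic,Hispanic or Latino,demographic
asian,asian,Asian,demographic
bmi,bmi,Body mass index,demographic
body mass index,bmi,Body mass index,demographic
weight,weight,Body weight,demographic
height,height,Body height,demographic
sbp,sbp,Systolic blood pressure,lab
systolic blood pressure,sbp,Systolic blood pressure,lab
dbp,dbp,Diastolic blood pressure,lab
diastolic blood pressure,dbp,Diastolic blood pressure,lab
hba1c,hba1c,Hemoglobin A1c,lab
hemoglobin a1c,hba1c,Hemoglobin A1c,lab
glycated hemoglobin,hba1c,Hemoglobin A1c,lab
fasting plasma glucose,fpg,Fasting plasma glucose,lab
fpg,fpg,Fasting plasma glucose,lab
ldl,ldl,LDL cholesterol,lab
ldl cholesterol,ldl,LDL cholesterol,lab
hdl,hdl,HDL cholesterol,lab
hdl cholesterol,hdl,HDL cholesterol,lab
total cholesterol,chol_total,Total cholesterol,lab
triglycerides,tg,Triglycerides,lab
creatinine,creatinine,Serum creatinine,lab
serum creatinine,creatinine,Serum creatinine,lab
egfr,egfr,Estimated GFR,lab
smoking,smoker,Current smoker,demographic
current smoker,smoker,Current smoker,demographic
diabetes duration,dm_duration,Diabetes duration,condition
duration of diabetes,dm_duration,Diabetes duration,condition
metformin,metformin,Metformin use,medication
insulin,insulin,Insulin use,medication
sulfonylurea,sulfonylurea,Sulfonylurea use,medication
guanidines,metformin,Metformin use,medication
statin,statin,Statin use,medication
aspirin,aspirin,Aspirin use,medication
hypertension,htn,Hypertension,condition
cardiovascular disease,cvd,Cardiovascular disease,condition
myocardial infarction,mi,Myocardial infarction,condition
stroke,stroke,Stroke,condition
heart failure,hf,Heart failure,condition
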