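# Default synthetic patient profile.
#
# Categorical frequencies approximate the breast-cancer registry mix a
# staging engine sees in practice; numeric features approximate adult
# survey-style distributions for the cohort-fit feature axes (age in years,
# blood pressures in mmHg, HbA1c in %, BMI in kg/m^2).  All generator
# parameters live here; none are hard-coded.
categorical:
  t:     {Tis: 0.06, T0: 0.04, T1: 0.35, T2: 0.30, T3: 0.15, T4: 0.10}
  n:     {N0: 0.45, N1mi: 0.05, N1: 0.25, N2: 0.15, N3: 0.10}
  m:     {M0: 0.90, M1: 0.10}
  grade: {G1: 0.30, G2: 0.40, G3: 0.30}
  her2:  {positive: 0.20, negative: 0.80}
  er:    {positive: 0.70, negative: 0.30}
  pr:    {positive: 0.60, negative: 0.40}
  sex:   {female: 0.99, male: 0.01}
  race:  {white: 0.60, african_american: 0.20, hispanic: 0.10, asian: 0.10}
numeric:
  age:   {dist: normal, mean: 61.0, sd: 12.0, min: 18.0, max: 95.0}
  sbp:   {dist: normal, mean: 134.0, sd: 17.0, min: 80.0, max: 220.0}
  dbp:   {dist: normal, mean: 79.0, sd: 11.0, min: 40.0, max: 130.0}
  hba1c: {dist: normal, mean: 7.3, sd: 1.5, min: 4.0, max: 15.0}
  bmi:   {dist: normal, mean: 31.0, sd: 6.0, min: 15.0, max: 60.0}
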