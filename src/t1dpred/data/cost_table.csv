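variable,category,physician_min,assistant_min,assay_usd,hcpcs,procedure,note
age,demographic,5,5,0.0,,blood_draw,recorded at the screening visit
log_age,demographic,5,5,0.0,,blood_draw,recorded at the screening visit
gender,demographic,5,5,0.0,,blood_draw,recorded at the screening visit
bmi,demographic,5,5,0.0,,blood_draw,anthropometry at the screening visit
bmi_z,demographic,5,5,0.0,,blood_draw,anthropometry at the screening visit
grs2,genetic,5,5,20.0,,blood_draw,genotyping array; assay price per published estimate
gada,immunological,5,5,24.0,86341,blood_draw,radioimmunoassay; package default price
iaa,immunological,5,5,19.0,86337,blood_draw,radioimmunoassay; package default price
ia2a_flag,immunological,5,5,24.0,86341,blood_draw,radioimmunoassay; package default price
ab_combination,immunological,5,5,67.0,86337 + 2 86341,blood_draw,all three autoantibody assays
fasting_cpeptide,metabolic,5,5,15.0,84681,blood_draw,single C-peptide assay; package default price
auc_glucose,metabolic,18.75,5,12.5,#82951 + 2 #82952,ogtt_120,assay bundle priced from the published per-variable total
auc_cpeptide,metabolic,18.75,5,75.0,5 #84681,ogtt_120,assay bundle priced from the published per-variable total
hba1c,metabolic,5,5,9.8,#83036,blood_draw,assay priced from the published per-variable total
index60,metabolic,12.5,5,8.2,#82952 + 2 #84681,ogtt_60,assay bundle priced from the published per-variable total
cpeptide30,metabolic,10,5,8.2,#82952 + 2 #84681,ogtt_30,assay bundle priced from the published per-variable total
beta2,metabolic,5,5,16.8,#82952 + #84681 + #83036,blood_draw,assay bundle priced from the published per-variable total
dptrs,classical,18.75,5,87.5,#82951 + 2 #82952 + 5 #84681,ogtt_120,full OGTT glucose and C-peptide panels
dptrs60,classical,12.5,5,40.0,#82951 + 3 #84681,ogtt_60,OGTT truncated at 60 min; package default price
m120,classical,18.75,5,17.5,#82951 + #84681,ogtt_120,120-min glucose and C-peptide
cph,classical,15,5,13.4,#82951 + #84681,ogtt_90,90-min OGTT; assay priced from the published model total
lr,classical,15,5,13.4,#82951 + #84681,ogtt_90,90-min OGTT; assay priced from the published model total
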