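trait_a,trait_b,type,value,se
rfi,feed_intake,rg,0.41,0.14
rfi,feed_intake,rp,0.54,0.03
rfi,mmwt,rg,-0.23,0.17
rfi,mmwt,rp,0.02,0.04
rfi,adg,rg,-0.09,0.17
rfi,adg,rp,-0.01,0.04
rfi,feeding_time_per_event,rg,0.17,0.14
rfi,feeding_time_per_event,rp,0.05,0.04
rfi,intake_per_event,rg,0.06,0.16
rfi,intake_per_event,rp,0.16,0.03
rfi,events_per_day,rg,0.13,0.16
rfi,events_per_day,rp,0.06,0.04
rfi,feeding_rate,rg,-0.25,0.19
rfi,feeding_rate,rp,0.11,0.03
rfi,c_start,rg,-0.15,0.17
rfi,c_start,rp,-0.20,0.03
rfi,c_final,rg,-0.14,0.15
rfi,c_final,rp,0.004,0.04
rfi,c_change,rg,-0.04,0.24
rfi,c_change,rp,0.20,0.03
rfi,visceral_fat,rg,-0.52,0.16
rfi,visceral_fat,rp,-0.11,0.05
rfi,subcutaneous_fat,rg,-0.33,0.19
rfi,subcutaneous_fat,rp,0.08,0.05
rfi,intermuscular_fat,rg,-0.30,0.18
rfi,intermuscular_fat,rp,-0.05,0.05
rfi,carcass_lean,rg,0.06,0.18
rfi,carcass_lean,rp,-0.06,0.05
rfi,carcass_fat,rg,-0.38,0.19
rfi,carcass_fat,rp,0.04,0.05
rfi,total_fat,rg,-0.58,0.18
rfi,total_fat,rp,-0.03,0.05
rfi,total_bone,rg,0.48,0.25
rfi,total_bone,rp,0.01,0.05
rfi,nonfat_visceral,rg,0.64,0.13
rfi,nonfat_visceral,rp,0.33,0.04
rfi,fat_lean_ratio,rg,-0.41,0.18
rfi,fat_lean_ratio,rp,0.07,0.05
rfi,carcass_weight,rg,-0.18,0.17
rfi,carcass_weight,rp,-0.26,0.05
rfi,dressing_out_pct,rg,-0.08,0.18
rfi,dressing_out_pct,rp,-0.20,0.05
ch4,rfi,rg,-0.28,0.16
ch4,rfi,rp,0.03,0.03
co2,rfi,rg,0.05,0.17
co2,rfi,rp,0.17,0.03
ch4_co2_mol,rfi,rg,0.04,0.17
ch4_co2_mol,rfi,rp,0.17,0.03
ch4_ratio,rfi,rg,-0.41,0.15
ch4_ratio,rfi,rp,-0.13,0.03
ch4,feed_intake,rg,0.33,0.17
ch4,feed_intake,rp,0.36,0.02
co2,feed_intake,rg,0.59,0.14
co2,feed_intake,rp,0.47,0.02
ch4_co2_mol,feed_intake,rg,0.60,0.14
ch4_co2_mol,feed_intake,rp,0.48,0.02
ch4_ratio,feed_intake,rg,-0.24,0.09
ch4_ratio,feed_intake,rp,-0.08,0.03
ch4,mmwt,rg,0.68,0.11
ch4,mmwt,rp,0.41,0.02
co2,mmwt,rg,0.62,0.13
co2,mmwt,rp,0.45,0.02
ch4_co2_mol,mmwt,rg,0.73,0.08
ch4_co2_mol,mmwt,rp,0.46,0.02
ch4_ratio,mmwt,rg,-0.06,0.08
ch4_ratio,mmwt,rp,-0.02,0.03
ch4,adg,rg,0.34,0.10
ch4,adg,rp,0.27,0.03
co2,adg,rg,0.06,0.19
co2,adg,rp,0.21,0.03
ch4_co2_mol,adg,rg,0.07,0.19
ch4_co2_mol,adg,rp,0.22,0.03
ch4_ratio,adg,rg,0.10,0.16
ch4_ratio,adg,rp,0.07,0.03
ch4,feeding_time_per_event,rg,0.04,0.16
ch4,feeding_time_per_event,rp,0.08,0.03
co2,feeding_time_per_event,rg,0.001,0.17
co2,feeding_time_per_event,rp,0.04,0.03
ch4_co2_mol,feeding_time_per_event,rg,0.004,0.17
ch4_co2_mol,feeding_time_per_event,rp,0.04,0.03
ch4_ratio,feeding_time_per_event,rg,0.02,0.15
ch4_ratio,feeding_time_per_event,rp,0.04,0.03
ch4,intake_per_event,rg,0.41,0.13
ch4,intake_per_event,rp,0.26,0.03
co2,intake_per_event,rg,0.22,0.16
co2,intake_per_event,rp,0.18,0.03
ch4_co2_mol,intake_per_event,rg,0.24,0.16
ch4_co2_mol,intake_per_event,rp,0.19,0.03
ch4_ratio,intake_per_event,rg,0.21,0.08
ch4_ratio,intake_per_event,rp,0.08,0.03
ch4,events_per_day,rg,-0.28,0.08
ch4,events_per_day,rp,-0.10,0.03
co2,events_per_day,rg,0.02,0.08
co2,events_per_day,rp,0.01,0.03
ch4_co2_mol,events_per_day,rg,0.01,0.08
ch4_co2_mol,events_per_day,rp,0.002,0.03
ch4_ratio,events_per_day,rg,-0.38,0.15
ch4_ratio,events_per_day,rp,-0.10,0.03
ch4,feeding_rate,rg,0.55,0.16
ch4,feeding_rate,rp,0.23,0.03
co2,feeding_rate,rg,0.25,0.21
co2,feeding_rate,rp,0.16,0.03
ch4_co2_mol,feeding_rate,rg,0.27,0.21
ch4_co2_mol,feeding_rate,rp,0.17,0.03
ch4_ratio,feeding_rate,rg,0.27,0.11
ch4_ratio,feeding_rate,rp,0.07,0.03
ch4,c_start,rg,-0.001,0.13
ch4,c_start,rp,-0.02,0.03
co2,c_start,rg,-0.35,0.14
co2,c_start,rp,-0.12,0.03
ch4_co2_mol,c_start,rg,-0.35,0.14
ch4_co2_mol,c_start,rp,-0.12,0.03
ch4_ratio,c_start,rg,0.27,0.10
ch4_ratio,c_start,rp,0.08,0.03
ch4,c_final,rg,-0.04,0.15
ch4,c_final,rp,-0.01,0.03
co2,c_final,rg,-0.33,0.15
co2,c_final,rp,-0.03,0.03
ch4_co2_mol,c_final,rg,-0.32,0.15
ch4_co2_mol,c_final,rp,-0.03,0.03
ch4_ratio,c_final,rg,0.06,0.08
ch4_ratio,c_final,rp,0.02,0.03
ch4,c_change,rg,-0.27,0.23
ch4,c_change,rp,-0.002,0.03
co2,c_change,rg,-0.17,0.25
co2,c_change,rp,0.09,0.03
ch4_co2_mol,c_change,rg,-0.17,0.25
ch4_co2_mol,c_change,rp,0.09,0.03
ch4_ratio,c_change,rg,-0.26,0.13
ch4_ratio,c_change,rp,-0.06,0.03
ch4,visceral_fat,rg,-0.13,0.16
ch4,visceral_fat,rp,-0.05,0.04
co2,visceral_fat,rg,-0.51,0.14
co2,visceral_fat,rp,-0.16,0.04
ch4_co2_mol,visceral_fat,rg,-0.51,0.14
ch4_co2_mol,visceral_fat,rp,-0.16,0.04
ch4_ratio,visceral_fat,rg,0.31,0.15
ch4_ratio,visceral_fat,rp,0.07,0.04
ch4,subcutaneous_fat,rg,-0.10,0.19
ch4,subcutaneous_fat,rp,0.03,0.04
co2,subcutaneous_fat,rg,-0.42,0.16
co2,subcutaneous_fat,rp,-0.14,0.04
ch4_co2_mol,subcutaneous_fat,rg,-0.44,0.17
ch4_co2_mol,subcutaneous_fat,rp,-0.14,0.04
ch4_ratio,subcutaneous_fat,rg,0.19,0.17
ch4_ratio,subcutaneous_fat,rp,0.11,0.04
ch4,intermuscular_fat,rg,-0.10,0.18
ch4,intermuscular_fat,rp,0.04,0.04
co2,intermuscular_fat,rg,-0.43,0.15
co2,intermuscular_fat,rp,-0.21,0.04
ch4_co2_mol,intermuscular_fat,rg,-0.43,0.15
ch4_co2_mol,intermuscular_fat,rp,-0.21,0.04
ch4_ratio,intermuscular_fat,rg,0.24,0.17
ch4_ratio,intermuscular_fat,rp,0.09,0.04
ch4,carcass_lean,rg,0.54,0.12
ch4,carcass_lean,rp,0.28,0.03
co2,carcass_lean,rg,0.65,0.11
co2,carcass_lean,rp,0.41,0.03
ch4_co2_mol,carcass_lean,rg,0.66,0.11
ch4_co2_mol,carcass_lean,rp,0.41,0.03
ch4_ratio,carcass_lean,rg,-0.03,0.17
ch4_ratio,carcass_lean,rp,-0.05,0.04
ch4,carcass_fat,rg,-0.11,0.18
ch4,carcass_fat,rp,0.01,0.04
co2,carcass_fat,rg,-0.46,0.16
co2,carcass_fat,rp,-0.17,0.04
ch4_co2_mol,carcass_fat,rg,-0.46,0.16
ch4_co2_mol,carcass_fat,rp,-0.17,0.04
ch4_ratio,carcass_fat,rg,0.24,0.18
ch4_ratio,carcass_fat,rp,0.12,0.04
ch4,total_fat,rg,-0.13,0.18
ch4,total_fat,rp,-0.01,0.04
co2,total_fat,rg,-0.57,0.15
co2,total_fat,rp,-0.19,0.04
ch4_co2_mol,total_fat,rg,-0.56,0.15
ch4_co2_mol,total_fat,rp,-0.19,0.04
ch4_ratio,total_fat,rg,0.33,0.17
ch4_ratio,total_fat,rp,0.11,0.04
ch4,total_bone,rg,-0.33,0.25
ch4,total_bone,rp,-0.07,0.04
co2,total_bone,rg,0.54,0.23
co2,total_bone,rp,0.08,0.04
ch4_co2_mol,total_bone,rg,0.52,0.23
ch4_co2_mol,total_bone,rp,0.07,0.04
ch4_ratio,total_bone,rg,-0.72,0.26
ch4_ratio,total_bone,rp,-0.09,0.03
ch4,nonfat_visceral,rg,0.36,0.17
ch4,nonfat_visceral,rp,0.12,0.04
co2,nonfat_visceral,rg,0.37,0.17
co2,nonfat_visceral,rp,0.20,0.04
ch4_co2_mol,nonfat_visceral,rg,0.39,0.17
ch4_co2_mol,nonfat_visceral,rp,0.21,0.04
ch4_ratio,nonfat_visceral,rg,-0.03,0.18
ch4_ratio,nonfat_visceral,rp,-0.03,0.04
ch4,fat_lean_ratio,rg,-0.12,0.17
ch4,fat_lean_ratio,rp,0.01,0.04
co2,fat_lean_ratio,rg,-0.51,0.14
co2,fat_lean_ratio,rp,-0.15,0.04
ch4_co2_mol,fat_lean_ratio,rg,-0.51,0.14
ch4_co2_mol,fat_lean_ratio,rp,-0.15,0.04
ch4_ratio,fat_lean_ratio,rg,0.30,0.16
ch4_ratio,fat_lean_ratio,rp,0.10,0.04
ch4,carcass_weight,rg,-0.22,0.16
ch4,carcass_weight,rp,-0.08,0.04
co2,carcass_weight,rg,0.15,0.17
co2,carcass_weight,rp,-0.06,0.04
ch4_co2_mol,carcass_weight,rg,0.13,0.17
ch4_co2_mol,carcass_weight,rp,-0.06,0.04
ch4_ratio,carcass_weight,rg,-0.28,0.16
ch4_ratio,carcass_weight,rp,-0.04,0.04
ch4,dressing_out_pct,rg,-0.24,0.16
ch4,dressing_out_pct,rp,-0.20,0.04
co2,dressing_out_pct,rg,0.23,0.17
co2,dressing_out_pct,rp,-0.08,0.04
ch4_co2_mol,dressing_out_pct,rg,0.21,0.17
ch4_co2_mol,dressing_out_pct,rp,-0.09,0.04
ch4_ratio,dressing_out_pct,rg,-0.33,0.15
ch4_ratio,dressing_out_pct,rp,-0.11,0.04
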