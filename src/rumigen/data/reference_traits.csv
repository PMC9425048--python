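table,trait,mean,sd,h2,h2_se,maternal_h2,maternal_h2_se,repeatability,repeatability_se
intake,rfi,-0.00094,1.328,0.42,0.09,,,,
intake,feed_intake,25.6,4.57,0.35,0.10,0.08,0.06,,
intake,mmwt,20.8,2.0,0.44,0.11,0.16,0.07,,
intake,adg,0.35,0.067,0.42,0.10,0.02,0.06,,
behavior,feeding_time_per_event,547.7,179.5,0.58,0.11,0.04,0.06,,
behavior,intake_per_event,203.8,69.92,0.47,0.09,,,,
behavior,events_per_day,13.67,4.427,0.44,0.09,,,,
behavior,feeding_rate,0.3846,0.105,0.29,0.10,0.08,0.06,,
ultrasound,c_start,3.85,1.156,0.39,0.11,0.06,0.06,,
ultrasound,c_final,4.58,1.37,0.57,0.09,,,,
ultrasound,c_change,0.74,1.097,0.15,0.07,,,,
ct,visceral_fat,5.13,1.33,0.93,0.19,0.01,0.09,,
ct,subcutaneous_fat,5.51,1.76,0.59,0.17,0.12,0.10,,
ct,intermuscular_fat,2.29,0.62,0.72,0.18,0.10,0.10,,
ct,carcass_lean,19.10,2.38,0.81,0.18,0.08,0.09,,
ct,carcass_fat,7.80,2.33,0.68,0.18,0.10,0.10,,
ct,total_fat,12.93,3.56,0.71,0.18,0.12,0.10,,
ct,total_bone,4.36,0.47,0.28,0.12,0.15,0.10,,
ct,nonfat_visceral,10.76,1.57,0.56,0.13,,,,
ct,fat_lean_ratio,0.67,0.15,0.82,0.19,0.08,0.10,,
ct,carcass_weight,31.26,4.52,0.77,0.14,,,,
ct,dressing_out_pct,48.81,2.16,0.82,0.14,,,,
gas,pac_bw,57.6,8.6,0.43,0.11,0.15,0.07,0.95,0.003
gas,ch4,17.2,3.51,0.32,0.08,0.01,0.04,0.31,0.03
gas,co2,1248,235,0.32,0.08,0.04,0.05,0.57,0.02
gas,ch4_co2_mol,29.4,5.44,0.31,0.08,0.04,0.05,0.57,0.02
gas,ch4_ratio,0.037,0.0070,0.29,0.06,,,0.32,0.03
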