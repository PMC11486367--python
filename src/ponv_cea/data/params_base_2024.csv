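name,role,value,low,high,se,dist,units,source
cost_ramosetron,cost,13.94,13.11,16.04,,gamma,USD,Ramosetron (0.3mg)
cost_metoclopramide,cost,0.27,0.25,0.30,,gamma,USD,Metoclopramide (10mg)
cost_dexamethasone,cost,1.60,1.36,1.83,,gamma,USD,Dexamethasone (5mg)
cost_palonosetron,cost,9.43,8.44,10.42,,gamma,USD,Palonosetron (0.075mg)
wage_physician_hourly,cost,53.92,48.24,59.62,,gamma,USD/h,Physician hourly wage
minutes_physician,time,2,1.80,2.20,,normal,min,Physician time for treating PONV
wage_nurse_hourly,cost,15.72,14.06,17.38,,gamma,USD/h,Nurse hourly wage
minutes_nurse,time,14,12.60,15.40,,normal,min,Nurse time for treating PONV
cost_hospital_day,cost,188.29,168.43,208.15,,gamma,USD/day,Cost per day of hospitalization due to PONV
additional_hospital_days,time,1.67,1.39,1.94,,normal,days,Additional days of hospitalization due to PONV
cost_outpatient_visit,cost,23.22,21.95,25.67,,gamma,USD,Cost per outpatient visit after discharge
n_outpatient_visits,count,0.67,0.62,0.71,,normal,visits,No. of outpatient visits after discharge
wage_patient_hourly,cost,13.09,11.71,14.47,,gamma,USD/h,Patient wage per hour
wage_loss_per_visit,cost,32.56,29.13,36.01,,gamma,USD,Wage loss per outpatient visit
wage_loss_per_day,cost,104.72,93.67,115.76,,gamma,USD,Wage loss per day of hospitalization
cost_transport_visit,cost,8.94,8.01,9.88,,gamma,USD,Cost of transportation per visit
horizon_days,time,5,4,6,,normal,days,Duration of analysis
utility_no_ponv,utility,0.90,0.7236,1.0,0.09,beta,utility,No PONV
utility_mild_ponv,utility,0.70,0.5628,0.8372,0.07,beta,utility,Mild PONV
utility_mod_severe_ponv,utility,0.24,0.2008,0.2792,0.02,beta,utility,Moderate-to-severe PONV
mild_share_ramosetron_acute,probability,0.7727,0.69543,0.84997,,beta,probability,Mild PONV 0-24h ramosetron
mild_share_no_antiemetic_acute,probability,0.7273,0.65457,0.80003,,beta,probability,Mild PONV 0-24h no antiemetics
mild_share_ramosetron_delayed,probability,0.7633,0.68697,0.83963,,beta,probability,Mild PONV 24-48h ramosetron
mild_share_no_antiemetic_delayed,probability,0.7018,0.63162,0.77198,,beta,probability,Mild PONV 24-48h no antiemetics
p_additional_stay_ramosetron,probability,0.0833,0.07497,0.09163,,beta,probability,Additional hospital stay ramosetron
p_additional_stay_no_antiemetic,probability,0.1333,0.11997,0.14663,,beta,probability,Additional hospital stay no antiemetics
p_outpatient_ramosetron,probability,0.0200,0.0180,0.0220,,beta,probability,Outpatient visit after discharge ramosetron
p_outpatient_no_antiemetic,probability,0.0200,0.0180,0.0220,,beta,probability,Outpatient visit after discharge no antiemetics
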