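parameter,score,condition,lower,lower_inclusive,upper,upper_inclusive,label
respiratory_effort,0,apnea_or_grunt,,,,,apnea or grunting
respiratory_effort,0,,0,true,40,false,bradypnea (<40/min)
respiratory_effort,1,,60,false,inf,false,tachypnea (>60/min) with or without retractions
respiratory_effort,2,,40,true,60,true,normal (40-60/min)
heart_rate,0,,0,true,100,false,bradycardia or asystole (<100/min)
heart_rate,1,,160,false,inf,false,tachycardia (>160/min)
heart_rate,2,,100,true,160,true,normal (100-160/min)
axillary_temperature,0,,-inf,false,36,false,hypothermia (<36 C)
axillary_temperature,1,,36,true,36.5,false,cold stress (36-36.5 C)
axillary_temperature,1,,37.5,false,inf,false,fever (>37.5 C)
axillary_temperature,2,,36.5,true,37.5,true,normothermia (36.5-37.5 C)
capillary_refill_time,0,,5,false,inf,false,CRT >5 s
capillary_refill_time,1,,3,true,5,true,CRT 3-5 s
capillary_refill_time,2,,0,true,3,false,CRT <3 s
random_blood_sugar,0,,0,true,40,false,hypoglycaemia (<40 mg/dl)
random_blood_sugar,1,,40,true,60,true,borderline (40-60 mg/dl)
random_blood_sugar,2,,60,false,inf,false,normal (>60 mg/dl)
spo2,0,,0,true,85,false,SpO2 <85%
spo2,1,,85,true,92,true,SpO2 85-92%
spo2,2,,92,false,100,true,SpO2 >92%
gestational_age,0,,0,true,32,false,<32 weeks
gestational_age,1,,32,true,37,false,32 to 36+6/7 weeks
gestational_age,2,,37,true,inf,false,37 weeks and above
birth_weight,0,,0,true,1.5,false,<1.5 kg
birth_weight,1,,1.5,true,2.5,false,1.5-2.49 kg
birth_weight,2,,2.5,true,inf,false,2.5 kg or above
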