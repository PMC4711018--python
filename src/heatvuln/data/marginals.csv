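stratum,variable,mean,sd,min,max
urban,age_ge60,5.44,1.69,1.25,10.14
urban,loss_labor_ability,0.23,0.19,0.00,1.04
urban,illiterate,19.90,10.54,2.50,63.12
urban,living_alone,7.35,4.72,0.90,21.30
urban,age_ge60_living_alone,0.47,0.41,0.00,2.65
urban,low_income,7.55,7.09,0.35,31.71
urban,low_income_seniors,1.20,1.59,0.01,6.82
urban,low_income_households,14.20,16.90,0.16,92.79
urban,households_one_room,21.86,12.73,0.83,61.07
urban,households_le8m2,5.28,4.46,0.17,19.89
rural,age_ge60,8.29,1.32,5.39,11.37
rural,loss_labor_ability,0.45,0.16,0.05,1.08
rural,illiterate,36.38,12.36,14.04,70.48
rural,living_alone,2.04,1.09,0.46,5.87
rural,age_ge60_living_alone,0.40,0.24,0.05,1.42
rural,low_income,10.17,3.03,1.45,17.47
rural,low_income_seniors,3.09,2.85,0.07,11.19
rural,low_income_households,13.29,5.91,1.50,30.05
rural,households_one_room,9.93,8.99,0.49,51.52
rural,households_le8m2,4.84,5.40,0.13,28.48
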