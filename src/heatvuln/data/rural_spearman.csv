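variable,age_ge60,loss_labor_ability,illiterate,living_alone,age_ge60_living_alone,low_income,low_income_seniors,low_income_households,households_one_room,households_le8m2
age_ge60,1.0,0.04,-0.3,0.02,0.13,0.16,-0.03,0.23,-0.36,-0.18
loss_labor_ability,0.04,1.0,-0.28,0.22,0.19,-0.16,-0.1,0.03,-0.21,-0.23
illiterate,-0.3,-0.28,1.0,-0.24,0.06,0.13,-0.06,0.07,0.38,0.33
living_alone,0.02,0.22,-0.24,1.0,0.75,-0.15,-0.08,-0.16,0.35,0.24
age_ge60_living_alone,0.13,0.19,0.06,0.75,1.0,0.05,-0.02,0.02,0.34,0.26
low_income,0.16,-0.16,0.13,-0.15,0.05,1.0,0.69,0.59,-0.33,-0.25
low_income_seniors,-0.03,-0.1,-0.06,-0.08,-0.02,0.69,1.0,0.39,-0.3,-0.25
low_income_households,0.23,0.03,0.07,-0.16,0.02,0.59,0.39,1.0,-0.27,-0.1
households_one_room,-0.36,-0.21,0.38,0.35,0.34,-0.33,-0.3,-0.27,1.0,0.74
households_le8m2,-0.18,-0.23,0.33,0.24,0.26,-0.25,-0.25,-0.1,0.74,1.0
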