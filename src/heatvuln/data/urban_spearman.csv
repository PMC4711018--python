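variable,age_ge60,loss_labor_ability,illiterate,living_alone,age_ge60_living_alone,low_income,low_income_seniors,low_income_households,households_one_room,households_le8m2
age_ge60,1.0,0.54,0.35,-0.04,0.4,0.02,0.13,0.11,-0.19,-0.08
loss_labor_ability,0.54,1.0,0.21,0.04,0.403,-0.12,0.02,-0.05,-0.24,-0.13
illiterate,0.35,0.21,1.0,-0.19,0.06,0.21,0.19,0.27,-0.15,-0.12
living_alone,-0.04,0.04,-0.19,1.0,0.45,-0.15,-0.1,-0.31,0.27,-0.04
age_ge60_living_alone,0.4,0.403,0.06,0.45,1.0,-0.11,-0.11,-0.15,-0.04,0.02
low_income,0.02,-0.12,0.21,-0.15,-0.11,1.0,0.68,0.89,-0.16,-0.07
low_income_seniors,0.13,0.02,0.19,-0.1,-0.11,0.68,1.0,0.74,-0.35,-0.2
low_income_households,0.11,-0.05,0.27,-0.31,-0.15,0.89,0.74,1.0,-0.35,-0.22
households_one_room,-0.19,-0.24,-0.15,0.27,-0.04,-0.16,-0.35,-0.35,1.0,0.63
households_le8m2,-0.08,-0.13,-0.12,-0.04,0.02,-0.07,-0.2,-0.22,0.63,1.0
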