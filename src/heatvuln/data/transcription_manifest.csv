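stratum,row_variable,col_variable,printed,recorded,note
urban,loss_labor_ability,age_ge60,0.54**,0.54,
urban,illiterate,age_ge60,0.35**,0.35,
urban,illiterate,loss_labor_ability,0.21,0.21,
urban,living_alone,age_ge60,-0.04,-0.04,
urban,living_alone,loss_labor_ability,0.04,0.04,
urban,living_alone,illiterate,-0.19,-0.19,
urban,age_ge60_living_alone,age_ge60,0.40**,0.4,
urban,age_ge60_living_alone,loss_labor_ability,0.403**,0.403,printed with an extra decimal digit; recorded as printed (0.403)
urban,age_ge60_living_alone,illiterate,0.06,0.06,
urban,age_ge60_living_alone,living_alone,0.45**,0.45,
urban,low_income,age_ge60,0.02,0.02,
urban,low_income,loss_labor_ability,-0.12,-0.12,
urban,low_income,illiterate,0.21,0.21,
urban,low_income,living_alone,-0.15,-0.15,
urban,low_income,age_ge60_living_alone,-0.11,-0.11,
urban,low_income_seniors,age_ge60,0.13,0.13,
urban,low_income_seniors,loss_labor_ability,0.02,0.02,
urban,low_income_seniors,illiterate,0.19,0.19,
urban,low_income_seniors,living_alone,-0.10,-0.1,
urban,low_income_seniors,age_ge60_living_alone,-0.11,-0.11,
urban,low_income_seniors,low_income,0.68**,0.68,
urban,low_income_households,age_ge60,0.11,0.11,
urban,low_income_households,loss_labor_ability,-0.05,-0.05,
urban,low_income_households,illiterate,0.27*,0.27,
urban,low_income_households,living_alone,-0.31**,-0.31,
urban,low_income_households,age_ge60_living_alone,-0.15,-0.15,
urban,low_income_households,low_income,0.89**,0.89,
urban,low_income_households,low_income_seniors,0.74**,0.74,
urban,households_one_room,age_ge60,-0.19,-0.19,
urban,households_one_room,loss_labor_ability,-0.24*,-0.24,
urban,households_one_room,illiterate,-0.15,-0.15,
urban,households_one_room,living_alone,0.27*,0.27,
urban,households_one_room,age_ge60_living_alone,-0.04,-0.04,
urban,households_one_room,low_income,-0.16,-0.16,
urban,households_one_room,low_income_seniors,-0.35**,-0.35,
urban,households_one_room,low_income_households,-0.35**,-0.35,
urban,households_le8m2,age_ge60,-0.08,-0.08,
urban,households_le8m2,loss_labor_ability,-0.13,-0.13,
urban,households_le8m2,illiterate,-0.12,-0.12,
urban,households_le8m2,living_alone,-0.04,-0.04,
urban,households_le8m2,age_ge60_living_alone,0.02,0.02,
urban,households_le8m2,low_income,-0.07,-0.07,
urban,households_le8m2,low_income_seniors,-0.20,-0.2,
urban,households_le8m2,low_income_households,-0.22,-0.22,
urban,households_le8m2,households_one_room,0.63**,0.63,
rural,loss_labor_ability,age_ge60,0.04**,0.04,suspected typo: starred p<=0.01 but value 0.04 is non-significant at n=73; recorded as printed
rural,illiterate,age_ge60,-0.30**,-0.3,
rural,illiterate,loss_labor_ability,-0.28*,-0.28,
rural,living_alone,age_ge60,0.02,0.02,
rural,living_alone,loss_labor_ability,0.22,0.22,
rural,living_alone,illiterate,-0.24*,-0.24,
rural,age_ge60_living_alone,age_ge60,0.13,0.13,
rural,age_ge60_living_alone,loss_labor_ability,0.19,0.19,
rural,age_ge60_living_alone,illiterate,0.06,0.06,
rural,age_ge60_living_alone,living_alone,0.75**,0.75,
rural,low_income,age_ge60,0.16,0.16,
rural,low_income,loss_labor_ability,-0.16,-0.16,
rural,low_income,illiterate,0.13,0.13,
rural,low_income,living_alone,-0.15,-0.15,
rural,low_income,age_ge60_living_alone,0.05,0.05,
rural,low_income_seniors,age_ge60,-0.03,-0.03,
rural,low_income_seniors,loss_labor_ability,-0.10,-0.1,
rural,low_income_seniors,illiterate,-0.06,-0.06,
rural,low_income_seniors,living_alone,-0.08,-0.08,
rural,low_income_seniors,age_ge60_living_alone,-0.02,-0.02,
rural,low_income_seniors,low_income,0.69**,0.69,
rural,low_income_households,age_ge60,0.23*,0.23,
rural,low_income_households,loss_labor_ability,0.03,0.03,
rural,low_income_households,illiterate,0.07,0.07,
rural,low_income_households,living_alone,-0.16,-0.16,
rural,low_income_households,age_ge60_living_alone,0.02,0.02,
rural,low_income_households,low_income,0.59**,0.59,
rural,low_income_households,low_income_seniors,0.39**,0.39,
rural,households_one_room,age_ge60,-0.36**,-0.36,
rural,households_one_room,loss_labor_ability,-0.21,-0.21,
rural,households_one_room,illiterate,0.38**,0.38,
rural,households_one_room,living_alone,0.35**,0.35,
rural,households_one_room,age_ge60_living_alone,0.34**,0.34,
rural,households_one_room,low_income,-0.33**,-0.33,
rural,households_one_room,low_income_seniors,-.30**,-0.3,printed without a leading zero (-.30); recorded as -0.30
rural,households_one_room,low_income_households,-0.27*,-0.27,
rural,households_le8m2,age_ge60,-0.18,-0.18,
rural,households_le8m2,loss_labor_ability,-0.23*,-0.23,
rural,households_le8m2,illiterate,0.33**,0.33,
rural,households_le8m2,living_alone,0.24*,0.24,
rural,households_le8m2,age_ge60_living_alone,0.26*,0.26,
rural,households_le8m2,low_income,-0.25*,-0.25,
rural,households_le8m2,low_income_seniors,-0.25*,-0.25,
rural,households_le8m2,low_income_households,-0.10,-0.1,
rural,households_le8m2,households_one_room,0.74**,0.74,
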