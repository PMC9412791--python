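programme,category,dalys
supervised,global_warming,1.81359E-06
supervised,stratospheric_ozone_depletion,2.0815E-10
supervised,ionising_radiation,1.19944E-09
supervised,particulate_matter_formation,5.67928E-11
supervised,photochemical_ozone_formation,5.23136E-09
supervised,cancer_effects,3.44848E-13
supervised,non_cancer_effects,1.30085E-15
supervised,water_consumption,1.78949E-06
supervised,total_dalys,3.60978E-06
supervised,daly_seconds,113.8380508
provision,global_warming,2.6799E-06
provision,stratospheric_ozone_depletion,1.7668E-10
provision,ionising_radiation,2.0407E-09
provision,particulate_matter_formation,1.4382E-10
provision,photochemical_ozone_formation,8.0968E-09
provision,cancer_effects,8.5907E-13
provision,non_cancer_effects,3.0017E-15
provision,water_consumption,6.1534E-06
provision,total_dalys,8.8438E-06
provision,daly_seconds,278.898726
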