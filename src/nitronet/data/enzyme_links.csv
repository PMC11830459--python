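id,source,target,process
e1,NO3-,NO2-,"nitrate reduction (DNRA / denitrification step 1)"
e2,NO2-,NH4+,"nitrite ammonification (DNRA step 2)"
e3,NO2-,NO,"nitrite reduction (denitrification / ANAMMOX)"
e4,NO,N2O,"nitric oxide reduction (denitrification)"
e5,N2O,N2,"nitrous oxide reduction (denitrification)"
e6,NH3,NH2OH,"ammonia monooxygenase (nitrification)"
e7,NH2OH,NO,"hydroxylamine oxidation (nitrification)"
e8,NO,NO2-,"nitric oxide oxidation (nitrification)"
e9,NO2-,NO3-,"nitrite oxidation (nitrification)"
e10,NH2OH,N2O,"hydroxylamine oxidation to nitrous oxide"
e11,NO,N2H4,"hydrazine synthase, NO branch (ANAMMOX)"
e12,NH4+,N2H4,"hydrazine synthase, ammonium branch (ANAMMOX)"
e13,N2H4,N2,"hydrazine dehydrogenase (ANAMMOX)"
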