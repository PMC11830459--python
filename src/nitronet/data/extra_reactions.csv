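id,stoich,category
AB1_NH3_protonation,H+:-1;NH3:-1;NH4+:1,acid_base
AB1r_NH4_deprotonation,H+:1;NH3:1;NH4+:-1,acid_base
AB2_NH2OH_protonation,H+:-1;NH2OH:-1;NH3OH+:1,acid_base
AB2r_NH3OH_deprotonation,H+:1;NH2OH:1;NH3OH+:-1,acid_base
AB3_N2H4_protonation,H+:-1;N2H4:-1;N2H5+:1,acid_base
AB3r_N2H5_deprotonation,H+:1;N2H4:1;N2H5+:-1,acid_base
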