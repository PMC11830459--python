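id,name,N,H,O,charge,dGf0_kJ_mol,role,source
NO3-,nitrate,1,0,3,-1,-111.3,nitrogen_species,"CRC Handbook 97th ed.; Thauer et al. 1977 Bacteriol Rev 41:100"
NO2-,nitrite,1,0,2,-1,-32.2,nitrogen_species,"CRC Handbook 97th ed.; Thauer et al. 1977 Bacteriol Rev 41:100"
NO,nitric oxide (aq),1,0,1,0,102.06,nitrogen_species,"Amend & Shock 2001 FEMS Microbiol Rev 25:175 (aqueous)"
N2O,nitrous oxide (aq),2,0,1,0,113.38,nitrogen_species,"Amend & Shock 2001 FEMS Microbiol Rev 25:175 (aqueous)"
N2,dinitrogen (aq),2,0,0,0,18.19,nitrogen_species,"Amend & Shock 2001 FEMS Microbiol Rev 25:175 (aqueous)"
NH2OH,hydroxylamine (aq),1,3,1,0,-23.4,nitrogen_species,"Stumm & Morgan 1996 Aquatic Chemistry 3rd ed."
NH3OH+,hydroxylammonium,1,4,1,1,-56.6,nitrogen_species,"Stumm & Morgan 1996 (consistent with pKa 5.8)"
N2H4,hydrazine (aq),2,4,0,0,128.1,nitrogen_species,"CRC Handbook 97th ed. (aqueous)"
N2H5+,hydrazinium,2,5,0,1,82.5,nitrogen_species,"CRC Handbook 97th ed. (consistent with pKa 8.0)"
NH4+,ammonium,1,4,0,1,-79.31,nitrogen_species,"CRC Handbook 97th ed.; Thauer et al. 1977"
NH3,ammonia (aq),1,3,0,0,-26.50,nitrogen_species,"CRC Handbook 97th ed. (consistent with pKa 9.25)"
O2,dioxygen (aq),0,0,2,0,16.44,oxygen,"Amend & Shock 2001 FEMS Microbiol Rev 25:175 (aqueous)"
H+,proton,0,1,0,1,0.0,proton,"convention"
H2O,water,0,2,1,0,-237.13,water,"CRC Handbook 97th ed."
e-,electron,0,0,0,-1,0.0,electron,"convention"
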