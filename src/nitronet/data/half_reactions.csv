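id,n_e,stoich
h01_NO3-_NO2-,2,H+:-2;H2O:1;NO2-:1;NO3-:-1;e-:-2
h02_NO3-_NO,3,H+:-4;H2O:2;NO:1;NO3-:-1;e-:-3
h03_NO3-_N2O,8,H+:-10;H2O:5;N2O:1;NO3-:-2;e-:-8
h04_NO3-_N2,10,H+:-12;H2O:6;N2:1;NO3-:-2;e-:-10
h05_NO3-_NH2OH,6,H+:-7;H2O:2;NH2OH:1;NO3-:-1;e-:-6
h06_NO3-_N2H4,14,H+:-16;H2O:6;N2H4:1;NO3-:-2;e-:-14
h07_NO3-_NH4+,8,H+:-10;H2O:3;NH4+:1;NO3-:-1;e-:-8
h08_NO2-_NO,1,H+:-2;H2O:1;NO:1;NO2-:-1;e-:-1
h09_NO2-_N2O,4,H+:-6;H2O:3;N2O:1;NO2-:-2;e-:-4
h10_NO2-_N2,6,H+:-8;H2O:4;N2:1;NO2-:-2;e-:-6
h11_NO2-_NH2OH,4,H+:-5;H2O:1;NH2OH:1;NO2-:-1;e-:-4
h12_NO2-_N2H4,10,H+:-12;H2O:4;N2H4:1;NO2-:-2;e-:-10
h13_NO2-_NH4+,6,H+:-8;H2O:2;NH4+:1;NO2-:-1;e-:-6
h14_NO_N2O,2,H+:-2;H2O:1;N2O:1;NO:-2;e-:-2
h15_NO_N2,4,H+:-4;H2O:2;N2:1;NO:-2;e-:-4
h16_NO_NH2OH,3,H+:-3;NH2OH:1;NO:-1;e-:-3
h17_NO_N2H4,8,H+:-8;H2O:2;N2H4:1;NO:-2;e-:-8
h18_NO_NH4+,5,H+:-6;H2O:1;NH4+:1;NO:-1;e-:-5
h19_N2O_N2,2,H+:-2;H2O:1;N2:1;N2O:-1;e-:-2
h20_N2O_NH2OH,4,H+:-4;H2O:-1;N2O:-1;NH2OH:2;e-:-4
h21_N2O_N2H4,6,H+:-6;H2O:1;N2H4:1;N2O:-1;e-:-6
h22_N2O_NH4+,8,H+:-10;H2O:1;N2O:-1;NH4+:2;e-:-8
h23_N2_NH2OH,2,H+:-2;H2O:-2;N2:-1;NH2OH:2;e-:-2
h24_N2_N2H4,4,H+:-4;N2:-1;N2H4:1;e-:-4
h25_N2_NH4+,6,H+:-8;N2:-1;NH4+:2;e-:-6
h26_NH2OH_N2H4,2,H+:-2;H2O:2;N2H4:1;NH2OH:-2;e-:-2
h27_NH2OH_NH4+,2,H+:-3;H2O:1;NH2OH:-1;NH4+:1;e-:-2
h28_N2H4_NH4+,2,H+:-4;N2H4:-1;NH4+:2;e-:-2
h29_NO3-_NH3,8,H+:-9;H2O:3;NH3:1;NO3-:-1;e-:-8
h30_NO2-_NH3,6,H+:-7;H2O:2;NH3:1;NO2-:-1;e-:-6
h31_NO_NH3,5,H+:-5;H2O:1;NH3:1;NO:-1;e-:-5
h32_N2O_NH3,8,H+:-8;H2O:1;N2O:-1;NH3:2;e-:-8
h33_N2_NH3,6,H+:-6;N2:-1;NH3:2;e-:-6
h34_NO_NH3OH+,3,H+:-4;NH3OH+:1;NO:-1;e-:-3
h35_N2_NH3OH+,2,H+:-4;H2O:-2;N2:-1;NH3OH+:2;e-:-2
h36_N2_N2H5+,4,H+:-5;N2:-1;N2H5+:1;e-:-4
h37_N2H5+_NH4+,2,H+:-3;N2H5+:-1;NH4+:2;e-:-2
h38_O2_H2O,4,H+:-4;H2O:2;O2:-1;e-:-4
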