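wavelength_nm,mua_water,mua_lactate,mua_lipid,mua_melanin,mus_skin,mus_fat
1310,0.12,0.29,0.18,2.75,4.9,10.57
1550,1.07,0.33,0.17,1.57,3.62,9.63
1650,0.48,0.35,0.15,1.27,3.25,9.47
1684,0.45,0.37,0.21,1.19,3.14,9.76
1730,0.61,0.37,0.42,1.09,3,13.74
1752,0.71,0.35,0.33,1.04,2.94,11.89
1920,11.45,0.33,0.5,0.77,2.52,14.63
2129,2.2,0.43,0.29,0.54,2.13,11.79
2259,1.72,0.54,0.29,0.45,1.94,15.69
2299,2.24,0.58,0.68,0.42,1.88,22.56
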