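compound,abbrev,AIE_eV,Eox_ac_V,Eox_aq_V,pH,Eox_aq2_V,pH2,pKa_plus1_r,pKa_zero_r,pKa_minus1_r
adenine,A,8.26,1.72,1.32,7.0,,,4.2,9.8,
thymine,T,8.87,1.87,1.29,7.0,,,,9.9,>13.0
guanine,G,7.77,1.25,1.04,7.0,0.89,10.2,3.1,9.2,12.2
cytosine,C,8.68,1.90,1.44,7.0,1.39,9.0,4.6,12.2,>13.0
uracil,U,9.32,>2.15,1.34,7.0,1.16,11.6,,9.5,
guanosine,rG,,,1.29,7.0,,,1.8,10.2,
1-methyl-guanine,1mG,,,1.06,7.0,,,3.2,10.4,
xanthine,X,,,0.93,7.0,,,1.2,7.5,11.0
hypoxanthine,hX,,,1.16,7.0,1.05,9.0,,8.9,12.1
1-methylindole,1mInd,7.40,,1.23,7.0,,,,,
indole,Ind,7.76,,1.24,7.0,,,,21.0,
phenol,PhOH,8.51,,1.35,7.0,,,,10.0,
thioanisole,tAn,7.93,,1.45,7.0,,,,,
4-methylaniline,4mAnl,7.37,0.78,,,,,5.1,,
anisole,An,8.24,1.62,,,,,,,
naphthalene,Napht,8.14,1.54,,,,,,,
caffeine,Caf,,1.20,1.45,6.0,,,0.7,,
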