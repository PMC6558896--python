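analyte,JEP,CAP,NIST2975,CB
Li,3,17,1/ND,3/ND
Mg,950,8655,291/281,ND/ND
Al,305,7973,5/ND,203/0
V,6,11,5/1,ND
Cr,17,146,90/102,ND
Mn,134,1251,1/11,1/ND
Fe,2788,5386,814/743,498/ND
Co,9,15,7/8,0/ND
Ni,200,249,55/65,0/ND
Cu,1147,14884,24/5,13/3
Zn,7433,31897,13926/17003,ND
Ga,1,3,ND,ND
As,4,5,1/2,ND/1
Se,5,14,ND/2,ND
Rb,7,8,ND,ND
Sr,44,427,8/1,2/1
Ag,62,35,ND,ND
Cd,6,3,ND,ND
In,ND,1,ND,ND
Cs,1,1,ND,ND
Ba,83,103,4/ND,3/3
Hg,4,26,ND,ND
Tl,ND,1,ND,ND
Pb,100,658,97/105,ND
Bi,3,11,1/1,ND
U,ND,2,1/1,ND
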