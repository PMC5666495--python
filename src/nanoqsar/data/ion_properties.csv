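oxide_formula,element,electronegativity,ionic_radius
Al2O3,Al,1.61,53.501
CeO2,Ce,1.12,86.9978
Co3O4,Co,1.88,65.0011
CoO,Co,1.88,70.0006
Cr2O3,Cr,1.66,60.9994
CuO,Cu,1.9,73.0
Fe2O3,Fe,1.83,64.4988
Fe3O4,Fe,1.83,71.9998
Gd2O3,Gd,1.2,93.5
HfO2,Hf,1.3,71.0
In2O3,In,1.78,79.9994
La2O3,La,1.1,103.1983
Mn2O3,Mn,1.55,58.0021
Ni2O3,Ni,1.91,55.999
NiO,Ni,1.91,69.0003
Sb2O3,Sb,2.05,76.0
SiO2,Si,1.9,40.0
SnO2,Sn,1.96,68.9999
TiO2,Ti,1.54,60.4992
WO3,W,2.36,60.0007
Y2O3,Y,1.22,90.0027
Yb2O3,Yb,1.1,86.8017
ZnO,Zn,1.65,74.0018
ZrO2,Zr,1.33,71.9995
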