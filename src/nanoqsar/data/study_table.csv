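# control_activity: 1.25
formula,hydro_size,density,rwz,ci,activity,subset
Al2O3,524.8,3.96,0.183,138.68,1.17,train
CeO2,321.3,7.3,0.178,109.13,1.1,test
Co3O4,247.6,6.07,0.212,229.74,1.25,train
CoO,378.3,6.4,0.144,247.41,1.17,train
Cr2O3,478.5,5.21,0.191,168.09,0.68,train
CuO,289.5,6.45,0.143,263.53,0.62,train
Fe2O3,385.2,5.25,0.194,216.0,1.15,train
Fe3O4,831.7,5.2,0.22,241.12,1.02,train
Gd2O3,726.7,7.41,0.227,134.64,1.1,train
HfO2,349.9,9.68,0.173,119.99,1.1,train
In2O3,303.2,7.18,0.21,253.47,1.17,train
La2O3,471.2,6.51,0.229,124.87,1.15,train
Mn2O3,525.9,4.55,0.202,139.35,1.08,train
Ni2O3,665.8,4.83,0.201,204.29,1.08,train
NiO,277.5,7.45,0.134,251.72,0.81,test
Sb2O3,459.9,5.19,0.238,319.39,1.15,test
SiO2,374.9,2.65,0.176,144.4,1.1,train
SnO2,635.0,7.01,0.173,265.07,1.17,train
TiO2,497.0,3.6,0.174,143.48,1.1,train
WO3,511.9,7.2,0.197,334.18,1.15,train
Y2O3,594.5,4.84,0.223,133.96,1.1,train
Yb2O3,682.6,9.25,0.217,105.03,1.1,test
ZnO,379.0,5.7,0.15,201.47,0.7,train
ZrO2,384.4,5.68,0.173,127.36,1.13,test
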