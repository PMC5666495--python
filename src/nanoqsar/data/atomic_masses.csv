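symbol,atomic_mass
Al,26.9815
Ce,140.116
Co,58.9332
Cr,51.9961
Cu,63.546
Fe,55.845
Gd,157.25
Hf,178.486
In,114.818
La,138.9055
Mn,54.938
Ni,58.6934
O,15.999
Sb,121.76
Si,28.085
Sn,118.71
Ti,47.867
W,183.84
Y,88.9058
Yb,173.045
Zn,65.38
Zr,91.224
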