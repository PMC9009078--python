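system,nucleus,delta_exp_ppm,PBE,TPSS,B3LYP,DLPNO-DSD-PBEP86,DLPNO-MP2
ala,H-a,3.82,26.91,27.28,27.23,27.23,27.09
ala,NH3,8.5,22.15,22.57,22.25,22.18,22.04
ala,H-b,1.38,29.43,29.81,29.67,29.63,29.52
gly,NH3,8.48,22.35,22.81,22.46,22.39,22.25
gly,H-a1,4.23,26.53,26.91,26.78,26.78,26.67
gly,H-a2,3.06,27.51,27.90,27.79,27.79,27.69
ser,H-a,3.64,27.05,27.41,27.42,27.43,27.32
ser,H-b1,3.75,27.03,27.45,27.38,27.34,27.21
ser,H-b2,4.46,26.28,26.75,26.67,26.66,26.51
ser,NH3,8.37,22.37,22.84,22.50,22.43,22.30
ser,OH,3.79,27.49,27.89,27.55,27.34,27.10
asp,COOH,15.57,15.00,15.45,14.96,14.81,14.58
asp,H-b1,3.27,26.86,27.33,27.21,27.21,27.09
asp,H-b2,2.54,27.73,28.13,28.00,28.01,27.81
asp,NH3,8.32,22.70,23.11,22.82,22.80,22.63
asp,H-a,3.76,27.56,27.95,27.90,27.87,27.69
cys,H-b1,3.55,27.44,27.90,27.80,27.82,27.69
cys,H-b2,2.78,28.11,28.50,28.50,28.43,28.23
cys,H-a,4.28,26.74,27.13,27.10,27.14,27.00
cys,NH3,8.65,22.24,22.70,22.36,22.34,22.20
cys,SH,1.92,28.09,28.57,28.46,28.32,28.19
thr,NH3,8.03,22.62,23.07,22.77,22.72,22.53
thr,H-a,4.02,26.79,27.17,27.11,27.11,26.93
thr,H-b,3.78,26.86,27.31,27.29,27.26,27.08
thr,OH,7.95,22.39,22.84,22.44,22.31,22.17
thr,H-g,1.39,29.53,29.92,29.78,29.69,29.59
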