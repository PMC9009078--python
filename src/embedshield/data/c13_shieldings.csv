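system,nucleus,delta_exp_ppm,PBE,TPSS,B3LYP,DLPNO-DSD-PBEP86,DLPNO-MP2
ala,C-a,50.92,122.75,128.71,122.55,134.94,137.95
ala,COO,177.71,-3.28,4.56,-8.58,7.33,12.23
ala,C-b,20.36,154.14,160.50,154.46,165.91,169.45
gly,COO,176.25,-1.78,5.92,-7.56,8.88,14.35
gly,C-a,43.58,132.05,137.97,131.45,142.82,145.77
ser,C-a,55.69,118.11,124.76,118.04,130.21,132.84
ser,C-b,62.86,107.61,115.51,109.22,121.68,124.33
ser,COO,175.05,0.13,7.86,-5.01,10.60,16.04
asp,COO,175.91,-1.05,6.80,-6.28,10.43,16.14
asp,C-a,53.78,116.04,122.71,116.32,129.40,133.00
asp,C-b,37.77,137.49,145.01,137.91,149.58,153.27
asp,COOH,174.66,3.73,11.35,-0.88,15.57,19.18
cys,C-b,28.09,143.55,149.91,144.50,157.26,160.78
cys,C-a,56.01,117.45,123.82,117.45,129.65,132.15
cys,COO,173.37,0.39,8.07,-5.52,10.50,15.74
thr,COO,172.06,-0.02,7.70,-5.85,10.90,16.65
thr,C-a,61.25,111.19,118.34,111.34,123.75,126.31
thr,C-b,66.93,102.23,109.40,103.91,116.63,118.81
thr,C-g,20.48,155.13,161.52,155.00,165.77,169.34
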