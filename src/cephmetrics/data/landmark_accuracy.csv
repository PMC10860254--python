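landmark,mre_mean,mre_sd,ci_low,ci_high,sdr_1mm,sdr_2mm,sdr_4mm,sdr_8mm
S,0.79,1.07,0.67,0.92,81.9,90.3,99.6,99.6
N,0.81,1.24,0.66,0.96,80.9,92.4,96.8,99.6
P,3.77,3.04,3.41,4.13,15.9,31.4,65.0,89.5
Ba,3.76,3.69,3.32,4.20,14.8,42.6,70.0,85.2
Or,1.77,1.29,1.62,1.92,24.5,71.1,94.2,99.6
Pt,3.18,3.42,2.78,3.59,13.4,47.3,78.3,90.6
Spp,1.39,3.41,0.99,1.80,64.6,83.0,92.8,99.6
Spa,2.58,3.80,2.13,3.02,26.7,53.4,85.9,96.0
A,1.58,1.63,1.38,1.77,40.4,74.4,94.6,99.6
Co,4.92,3.26,4.54,5.31,11.2,27.4,45.8,72.9
DC,2.53,2.81,2.20,2.87,28.5,58.8,84.1,93.1
R1,3.50,3.96,3.03,3.97,18.4,48.0,76.9,87.4
R2,2.76,2.48,2.46,3.05,26.7,45.8,80.5,94.6
R3,3.96,3.41,3.56,4.36,6.5,30.7,69.0,88.8
R4,5.86,3.30,5.47,6.25,10.1,18.4,36.1,65.0
Xi,3.19,2.16,2.94,3.45,13.4,38.3,63.5,98.2
hT,2.89,1.92,2.66,3.12,17.0,39.0,74.0,97.5
Me,1.78,2.81,1.45,2.11,56.3,78.7,90.6,96.0
Po,1.29,0.96,1.17,1.40,46.2,80.9,98.2,100.0
B,1.36,1.17,1.22,1.50,49.5,77.6,96.8,99.6
Pm,1.19,0.98,1.07,1.30,50.9,84.1,99.3,100.0
Gnk,0.81,0.96,0.69,0.92,79.8,93.9,97.1,100.0
UpIe,0.37,0.19,0.35,0.39,99.6,100.0,100.0,100.0
UpIa,1.11,1.08,0.98,1.24,61.7,88.1,97.5,99.6
LoIe,0.28,0.16,0.26,0.30,99.6,100.0,100.0,100.0
LoIa,1.30,0.98,1.19,1.42,43.0,84.5,97.5,100.0
1UpMdc,1.69,2.52,1.39,1.99,53.4,77.3,91.3,97.5
1UpMma,1.60,2.18,1.34,1.86,40.4,84.8,96.0,96.8
Ap,0.61,0.47,0.55,0.66,83.0,98.9,100.0,100.0
Sn,0.67,0.58,0.60,0.74,83.8,97.5,99.3,100.0
UpL,1.31,1.15,1.17,1.44,54.2,78.7,96.8,100.0
LoL,0.94,0.86,0.84,1.05,67.1,92.8,99.3,100.0
Pom,2.05,1.37,1.88,2.21,27.8,54.5,91.3,99.6
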