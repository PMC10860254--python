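landmark,image,x,y,icc
S,A,588.88,152.56,1
N,A,934.58,126.09,1
P,A,468.58,220.84,0.99
Ba,A,453.87,309.68,1
Or,A,853.62,256.17,1
Pt,A,666.47,223.62,1
Spp,A,685.18,339.47,0.99
Spa,A,925.97,379.03,1
A,A,908.00,389.21,1
Co,A,526.21,247.91,0.99
DC,A,537.95,277.44,1
R1,A,681.03,385.09,0.99
R2,A,542.76,372.39,1
R3,A,602.15,311.73,0.99
R4,A,585.33,494.85,0.98
Xi,A,609.52,404.73,0.98
hT,A,599.22,502.05,1
Me,A,828.56,609.04,1
Po,A,860.81,580.67,1
B,A,864.70,527.11,0.99
Pm,A,862.51,556.61,1
Gnk,A,854.28,621.05,1
UpIe,A,914.55,480.74,1
UpIa,A,883.65,376.10,1
LoIe,A,895.17,452.82,1
LoIa,A,834.90,527.52,1
1UpMdc,A,738.83,413.65,1
1UpMma,A,799.05,353.53,1
Ap,A,1058.36,337.83,1
Sn,A,993.00,396.88,1
UpL,A,979.41,460.86,1
LoL,A,956.21,497.29,1
Pom,A,927.67,596.93,1
S,B,1360.58,217.19,1
N,B,1824.02,179.64,1
P,B,1197.60,313.30,0.99
Ba,B,1192.49,473.38,1
Or,B,1703.35,375.07,1
Pt,B,1463.15,328.32,1
Spp,B,1485.33,494.78,0.99
Spa,B,1844.84,522.46,1
A,B,1796.58,550.87,1
Co,B,1271.20,342.25,0.99
DC,B,1280.59,432.39,1
R1,B,1467.46,568.39,0.99
R2,B,1260.77,542.93,1
R3,B,1374.88,479.39,0.99
R4,B,1350.11,715.36,0.98
Xi,B,1361.74,598.12,0.98
hT,B,1344.90,769.04,1
Me,B,1698.74,868.92,1
Po,B,1736.28,830.39,1
B,B,1727.95,756.28,0.99
Pm,B,1734.57,796.98,1
Gnk,B,1729.89,877.71,1
UpIe,B,1825.77,683.21,1
UpIa,B,1756.35,550.53,1
LoIe,B,1771.70,638.02,1
LoIa,B,1682.84,760.65,1
1UpMdc,B,1542.13,600.51,1
1UpMma,B,1635.35,515.25,1
Ap,B,1993.68,469.87,1
Sn,B,1909.98,550.54,1
UpL,B,1913.15,636.74,1
LoL,B,1870.12,715.84,1
Pom,B,1792.92,847.70,1
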