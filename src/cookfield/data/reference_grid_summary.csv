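h_cm,d_cm,n,mean_ut,sd_ut,gm_ut,gsd,q1_ut,median_ut,q3_ut
20,0,45,1.93,1.82,1.36,2.29,0.65,1.22,2.33
20,10,45,0.81,0.61,0.63,2.00,0.39,0.63,1.04
20,20,45,0.36,0.23,0.31,1.77,0.21,0.33,0.412
20,30,45,0.20,0.12,0.17,1.66,0.13,0.17,0.24
10,0,45,2.88,2.18,2.22,2.10,1.41,2.03,3.83
10,10,45,0.81,0.45,0.71,1.71,0.55,0.69,0.99
10,20,45,0.35,0.19,0.31,1.70,0.22,0.31,0.445
10,30,45,0.20,0.10,0.17,1.64,0.12,0.19,0.25
0,0,45,3.86,3.31,2.88,2.24,1.77,2.96,5.11
0,10,45,1.06,0.70,0.84,2.07,0.59,0.94,1.39
0,20,45,0.43,0.25,0.36,1.96,0.25,0.41,0.60
0,30,45,0.23,0.13,0.19,1.87,0.11,0.21,0.31
-10,0,45,2.154,2.010,1.39,2.84,0.74,1.64,2.55
-10,10,45,0.917,0.746,0.68,2.25,0.36,0.80,1.15
-10,20,45,0.436,0.275,0.35,1.99,0.20,0.38,0.63
-10,30,45,0.226,0.144,0.19,1.87,0.11,0.21,0.32
-20,0,45,2.092,2.059,1.20,3.27,0.46,1.52,2.93
-20,10,45,0.732,0.602,0.52,2.41,0.23,0.59,1.05
-20,20,45,0.358,0.270,0.276,2.09,0.15,0.29,0.53
-20,30,45,0.198,0.132,0.162,1.90,0.10,0.18,0.26
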