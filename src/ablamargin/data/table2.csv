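patient_id,group,dta_rigid,dta_deformed,pct_rigid,pct_deformed,cc_rigid,cc_deformed
1,LTP,0.00,0.00,91.30,4.00,1.05,0.25
2,LTP,0.53,0.07,2.74,0.00,0.05,0.00
3,LTP,0.00,0.10,0.66,0.00,0.02,0.00
4,LTP,0.25,0.00,0.00,0.00,0.00,0.00
5,LTP,0.00,0.05,24.95,0.00,1.03,0.00
6,LTP,0.24,0.00,16.90,0.58,0.52,0.01
7,LTP,0.00,0.00,2.39,3.47,0.03,0.04
8,LTP,0.00,0.47,18.07,0.00,0.56,0.00
9,LTP,0.00,0.00,70.96,17.65,1.58,0.37
10,LTP,0.00,0.17,11.68,0.00,0.21,0.00
11,LTP,0.00,0.00,17.10,0.21,0.57,0.01
12,LTP,0.00,0.00,68.01,12.01,3.99,0.48
13,LTP,0.10,0.00,0.00,0.00,0.00,0.00
14,LTP,0.00,0.24,11.09,2.50,0.18,0.05
1,LTP-free,0.40,0.60,49.16,0.00,0.34,0.00
2,LTP-free,0.00,0.61,100.00,0.00,0.96,0.00
3,LTP-free,0.27,0.24,0.00,0.00,0.00,0.00
4,LTP-free,0.00,0.48,2.72,0.00,0.06,0.00
5,LTP-free,0.17,0.20,0.00,0.00,0.00,0.00
6,LTP-free,0.10,0.45,0.00,0.00,0.00,0.00
7,LTP-free,0.15,0.28,0.00,0.00,0.00,0.00
8,LTP-free,0.00,0.30,35.24,0.39,3.20,0.04
9,LTP-free,0.24,0.45,0.00,0.00,0.00,0.00
10,LTP-free,0.00,0.52,41.19,0.89,1.10,0.03
11,LTP-free,0.07,0.24,0.00,0.00,0.00,0.00
12,LTP-free,0.00,0.07,0.00,0.00,0.00,0.00
13,LTP-free,0.00,0.14,14.10,0.00,0.06,0.00
14,LTP-free,0.20,0.20,0.00,0.00,0.00,0.00
15,LTP-free,0.00,0.30,2.32,0.00,0.04,0.00
16,LTP-free,0.00,0.00,4.86,0.00,0.06,0.00
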