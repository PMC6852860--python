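trait,marker,genotype,lsm,overall_p
DTRW2,LEP,CC,231.47,0.001
DTRW2,LEP,CT,220.37,0.001
DTRW2,LEP,TT,214.13,0.001
DTRW3,LEP,CC,328.73,0.008
DTRW3,LEP,CT,329.50,0.008
DTRW3,LEP,TT,314.10,0.008
DTRW3,FABP4_3691,AA,348.11,0.037
DTRW3,FABP4_3691,GA,312.91,0.037
DTRW3,FABP4_3691,GG,311.23,0.037
DTRW3,GHR,AA,315.24,0.034
DTRW3,GHR,GA,328.30,0.034
DTRW3,GHR,GG,328.74,0.034
DTRW4,CAPN1_316,CC,474.54,0.005
DTRW4,CAPN1_316,GC,428.14,0.005
DTRW4,CAPN1_316,GG,447.82,0.005
DTRW5,LEP,CC,499.40,0.006
DTRW5,LEP,CT,494.26,0.006
DTRW5,LEP,TT,477.59,0.006
W2-W3 FP,FABP4_2834,CC,101.87,0.015
W2-W3 FP,FABP4_2834,GC,97.48,0.015
W2-W3 FP,FABP4_2834,GG,93.13,0.015
W2-W3 FP,LGB,AA,93.22,0.047
W2-W3 FP,LGB,AB,99.14,0.047
W2-W3 FP,LGB,BB,100.12,0.047
W2-W3 FP,GHR,AA,93.44,0.006
W2-W3 FP,GHR,GA,99.84,0.006
W2-W3 FP,GHR,GG,99.20,0.006
W4-W5 FP,GHR,AA,82.87,0.019
W4-W5 FP,GHR,GA,88.67,0.019
W4-W5 FP,GHR,GG,75.98,0.019
FW,CAPN1_316,CC,405.34,0.003
FW,CAPN1_316,GC,445.12,0.003
FW,CAPN1_316,GG,448.65,0.003
W2-W3 DMI,CAST,CC,638.62,0.042
W2-W3 DMI,CAST,GC,641.40,0.042
W2-W3 DMI,CAST,GG,610.84,0.042
W2-W3 DMI,GHR,AA,607.85,0.006
W2-W3 DMI,GHR,GA,640.73,0.006
W2-W3 DMI,GHR,GG,642.30,0.006
TDMI,LEP,CC,4017,0.018
TDMI,LEP,CT,4150,0.018
TDMI,LEP,TT,3965,0.018
TDMI,IGF1,CC,4020,0.020
TDMI,IGF1,CT,3981,0.020
TDMI,IGF1,TT,4131,0.020
TDMI,GHR,AA,4213,0.000
TDMI,GHR,GA,4017,0.000
TDMI,GHR,GG,3902,0.000
W1-W2 DDMI,FABP4_3533,AA,4.63,0.004
W1-W2 DDMI,FABP4_3533,TA,4.64,0.004
W1-W2 DDMI,FABP4_3533,TT,4.89,0.004
W4-W5 DDMI,MYF5,AA,8.74,0.034
W4-W5 DDMI,MYF5,GA,9.13,0.034
W4-W5 DDMI,MYF5,GG,8.75,0.034
W4-W5 DDMI,GHR,AA,8.87,0.040
W4-W5 DDMI,GHR,GA,8.55,0.040
W4-W5 DDMI,GHR,GG,9.19,0.040
TDDMI,LEP,CC,8.49,0.000
TDDMI,LEP,CT,8.02,0.000
TDDMI,LEP,TT,7.78,0.000
TDDMI,FABP4_3533,AA,8.33,0.011
TDDMI,FABP4_3533,TA,7.91,0.011
TDDMI,FABP4_3533,TT,8.05,0.011
TDDMI,IGF1,CC,8.02,0.020
TDDMI,IGF1,CT,7.97,0.020
TDDMI,IGF1,TT,8.29,0.020
TDDMI,LGB,AA,8.37,0.012
TDDMI,LGB,AB,7.92,0.012
TDDMI,LGB,BB,7.99,0.012
W2-W3 FCR,CAST,CC,6.41,0.023
W2-W3 FCR,CAST,GC,6.43,0.023
W2-W3 FCR,CAST,GG,6.10,0.023
W2-W3 FCR,GHR,AA,6.01,0.004
W2-W3 FCR,GHR,GA,6.43,0.004
W2-W3 FCR,GHR,GG,6.42,0.004
W3-W4 FCR,OLR1,AA,6.02,0.024
W3-W4 FCR,OLR1,AC,6.59,0.024
W4-W5 FCR,FABP4_3533,AA,13.85,0.031
W4-W5 FCR,FABP4_3533,TA,13.02,0.031
W4-W5 FCR,FABP4_3533,TT,13.73,0.031
TFCR,LEP,CC,9.63,0.048
TFCR,LEP,CT,9.64,0.048
TFCR,LEP,TT,9.27,0.048
TFCR,IGF1,CC,9.63,0.004
TFCR,IGF1,CT,9.72,0.004
TFCR,IGF1,TT,9.21,0.004
TFCR,CAPN1_316,CC,10.27,0.001
TFCR,CAPN1_316,GC,9.09,0.001
TFCR,CAPN1_316,GG,9.03,0.001
W2-W3 ADWG,FABP4_2834,CC,1.02,0.019
W2-W3 ADWG,FABP4_2834,GC,1.06,0.019
W2-W3 ADWG,FABP4_2834,GG,1.11,0.019
W2-W3 ADWG,LGB,AA,1.11,0.036
W2-W3 ADWG,LGB,AB,1.05,0.036
W2-W3 ADWG,LGB,BB,1.03,0.036
W2-W3 ADWG,GHR,AA,1.11,0.009
W2-W3 ADWG,GHR,GA,1.05,0.009
W2-W3 ADWG,GHR,GG,1.04,0.009
W4-W5 ADWG,FABP4_3533,AA,1.16,0.019
W4-W5 ADWG,FABP4_3533,TA,1.31,0.019
W4-W5 ADWG,FABP4_3533,TT,1.21,0.019
W4-W5 ADWG,GHR,AA,1.22,0.047
W4-W5 ADWG,GHR,GA,1.15,0.047
W4-W5 ADWG,GHR,GG,1.33,0.047
TADWG,CAPN1_316,CC,0.84,0.007
TADWG,CAPN1_316,GC,0.92,0.007
TADWG,CAPN1_316,GG,0.92,0.007
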