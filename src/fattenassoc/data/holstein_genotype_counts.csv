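marker,allele_first,allele_second,n_hom_first,n_het,n_hom_second
LEP,C,T,43,45,208
FABP4_3691,A,G,11,125,160
FABP4_2834,C,G,32,185,79
FABP4_3533,A,T,42,180,74
DGAT1,A,K,44,200,52
TG,C,T,238,46,12
IGF1,C,T,33,194,69
IGF1R,A,B,133,121,42
MYF5,A,G,10,143,143
LGB,A,B,36,191,69
CAPN1_316,C,G,18,137,141
CAPN1_530,A,G,10,81,205
CAST,C,G,90,156,50
GHR,A,G,196,68,32
OLR1,A,C,70,226,0
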