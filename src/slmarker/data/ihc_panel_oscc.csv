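stain_id,protein,compartment,under_rule,over_rule
BRCA1(N),BRCA1,N,<1+,>=1+
CDH3(C),CDH3,C,<1+,>=1+
CDH3(N),CDH3,N,<1+,>=1+
CDK6(C),CDK6,C,<=1+,>1+
CSNK1E(C),CSNK1E,C,<=1+,>1+
EGFR(C),EGFR,C,<=1+,>1+
EGFR(M),EGFR,M,<1+ and <10%,>=1+ and >=10%
FEN1(C),FEN1,C,<1+,>=1+
FLNA(C),FLNA,C,<1+,>=1+
FLNA(N),FLNA,N,<=1+,>1+
KRAS(C),KRAS,C,<1+,>=1+
MET(C),MET,C,<=1+,>1+
MSH2(N),MSH2,N,<1+,>=1+
P16(C),P16,C,<=1+,>1+
P16(N),P16,N,<1+,>=1+
PARP1(N),PARP1,N,<1+,>=1+
PIM1(C),PIM1,C,<3+,>=3+
PIM1(N),PIM1,N,<3+,>=3+
PLK1(C),PLK1,C,<3+,>=3+
POLB(C),POLB,C,<=1+,>1+
POLB(N),POLB,N,<=1+,>1+
RAD54B(N),RAD54B,N,<1+,>=1+
RB1(N),RB1,N,<1+,>=1+
SGK2(C),SGK2,C,<=1+,>1+
SHC1(C),SHC1,C,<1+,>=1+
SHC1(N),SHC1,N,<=1+,>1+
STK17A(C),STK17A,C,<=1+,>1+
STK17A(N),STK17A,N,<=1+,>1+
TP53(N),TP53,N,<=0%,>0%
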