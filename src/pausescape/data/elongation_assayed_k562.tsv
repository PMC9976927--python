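factor
POLR2A
POLR2B
POLR2G
POLR2H
MLLT1
SUPT5H
GTF2F1
BRD4
WDR43
NCBP2
HNRNPU
LARP7
MYC
TAF1
TBP
AFF1
EZH2
PAF1
SSRP1
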