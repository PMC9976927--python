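factor	complex
CCNT1	SEC
CCNT2	SEC
ELL	SEC
ELL2	SEC
ELL3	SEC
AFF1	SEC
AFF4	SEC
MLLT1	SEC
MLLT3	SEC
NELFA	NELF
NELFB	NELF
NELFCD	NELF
NELFE	NELF
SUPT4H1	DSIF
SUPT5H	DSIF
SUPT6H	established
SUPT16H	established
BRD4	established
MYC	established
TAF1	established
TBP	established
PAF1	established
CDK9	P-TEFb
LARP7	7SK-snRNP
HEXIM1	7SK-snRNP
HEXIM2	7SK-snRNP
MEPCE	7SK-snRNP
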