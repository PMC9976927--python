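factor
AQR
SSB
HNRNPK
DGCR8
PCBP1
ATF
ZNF800
XRCC6
NCBP2
SBDS
YWHAG
GRWD1
ZNF622
SRSF7
TARDBP
BUD13
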