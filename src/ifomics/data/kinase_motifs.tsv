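# Simplified literature-consensus kinase substrate motifs (synthetic test
# catalog; offset:allowed-residues relative to the phosphoacceptor at 0).
PKA	-3:R	-2:R	0:ST
PKC	0:ST	2:RK
PKG	-3:R	-2:K	0:ST
CK2	0:ST	3:DE
CAMK2	-3:R	0:ST
AKT	-5:R	-3:R	0:ST
AMPK	-4:LMI	-3:RK	0:ST
GSK3	0:ST	4:S
CDK	0:ST	1:P	3:KR
MAPK	-2:P	0:ST	1:P
PLK	-2:DE	0:ST
ATM_ATR	0:ST	1:Q
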