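# enzyme	recognition (IUPAC, written 5'->3')
BauI	CACGAG
NaeI	GCCGGC
EcoRI	GAATTC
BamHI	GGATCC
HindIII	AAGCTT
HincII	GTYRAC
NheI	GCTAGC
XbaI	TCTAGA
SmaI	CCCGGG
MluI	ACGCGT
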