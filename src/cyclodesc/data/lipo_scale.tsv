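#code	name	normalized	sasa_max
ALA	Ala	0.015	65.85
ARG	Arg+	-0.62	200.62
ASN	Asn	-0.18	128.88
ASP	Asp-	-0.51	112.53
CYS	Cys	0.068	99.87
GLN	Gln	-0.14	148.60
GLU	Glu-	-0.47	146.78
GLY	Gly	0.00	0.00
HIS	His	-0.060	157.99
ILE	Ile	0.38	157.72
LEU	Leu	0.19	166.64
LYS	Lys+	-0.366	195.16
MET	Met	0.096	166.80
PHE	Phe	0.26	188.38
PRO	Pro	0.25	105.72
SER	Ser	-0.083	82.22
THR	Thr	-0.015	114.60
TRP	Trp	0.28	229.66
TYR	Tyr	0.19	214.65
VAL	Val	0.20	125.98
ACK	Ack	0.012	263.09
CDR	Cdr+	-0.49	336.44
KYW	Kyw	0.10	236.08
MEE	Mee	-0.012	182.28
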