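# name	site	cut_offset
EcoRI	GAATTC	1
BamHI	GGATCC	1
HindIII	AAGCTT	1
XbaI	TCTAGA	1
XhoI	CTCGAG	1
SalI	GTCGAC	1
PstI	CTGCAG	5
SacI	GAGCTC	5
KpnI	GGTACC	5
SmaI	CCCGGG	3
EcoRV	GATATC	3
HpaI	GTTAAC	3
DraI	TTTAAA	3
SspI	AATATT	3
ScaI	AGTACT	3
StuI	AGGCCT	3
NdeI	CATATG	2
NcoI	CCATGG	1
NheI	GCTAGC	1
SpeI	ACTAGT	1
BglII	AGATCT	1
ApaI	GGGCCC	5
NsiI	ATGCAT	5
SphI	GCATGC	5
AflII	CTTAAG	1
ClaI	ATCGAT	2
BstBI	TTCGAA	2
AccI	GTMKAC	2
AvaII	GGWCC	1
DdeI	CTNAG	1
HinfI	GANTC	1
AluI	AGCT	2
HaeIII	GGCC	2
RsaI	GTAC	2
TaqI	TCGA	1
MseI	TTAA	1
Sau3AI	GATC	0
HhaI	GCGC	3
MspI	CCGG	1
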