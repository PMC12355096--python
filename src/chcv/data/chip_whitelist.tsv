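kind	gene	hgvs_p	consequences	note
site	DNMT3A	p.R882H	missense	hotspot
site	DNMT3A	p.R882C	missense	hotspot
site	TET2	p.H1904R	missense	catalytic; exempt from binomial test
site	TET2	p.I1873T	missense	catalytic; exempt from binomial test
site	TET2	p.T1884A	missense	catalytic; exempt from binomial test
site	JAK2	p.V617F	missense	hotspot
site	SF3B1	p.K700E	missense	hotspot
site	SF3B1	p.K666N	missense	hotspot
site	SF3B1	p.G742D	missense	hotspot
site	SF3B1	p.E622D	missense	hotspot
site	SRSF2	p.P95H	missense	hotspot
site	SRSF2	p.P95L	missense	hotspot
site	SRSF2	p.P95R	missense	hotspot
site	SRSF2	p.P95T	missense	hotspot
site	GNB1	p.K57E	missense	hotspot
site	GNAS	p.R201C	missense	hotspot
site	GNAS	p.R201H	missense	hotspot
site	GNAS	p.R844H	missense	hotspot
site	TP53	p.R175H	missense	hotspot
site	TP53	p.R248Q	missense	hotspot
site	TP53	p.R273H	missense	hotspot
site	TP53	p.R282W	missense	hotspot
site	TP53	p.P72R	missense	matches list; removed downstream as named artifact
site	ASXL1	p.P815L	missense	matches list; removed downstream as named artifact
rule	DNMT3A	*	missense	any missense (germline excluded by binomial test)
rule	DNMT3A	*	frameshift,nonsense,splice	loss of function
rule	TET2	*	frameshift,nonsense,splice	loss of function
rule	ASXL1	*	frameshift,nonsense,splice	loss of function
rule	PPM1D	*	frameshift,nonsense,splice	loss of function (exon 5/6 truncation)
rule	CBL	*	frameshift,nonsense,splice	loss of function
rule	TP53	*	frameshift,nonsense,splice	loss of function
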