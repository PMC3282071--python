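case_id	hgvs_c	protein_change	inheritance	height_sd	ofc_sd	learning_disability	malignancy	discovery_case
1	c.401T>C	p.M134T	de_novo	+2.2	+0.3	mild		false
2	c.466A>G	p.K156E	familial	+3.3	+1.5	mild		false
3	c.836A>G	p.H279R	de_novo	+2.6	+2.3	mild		true
4	c.1876G>A	p.V626M	de_novo	+3.6	+3.2	no		false
5	c.1915A>G	p.K639E	de_novo	+6	+4.9	moderate		false
6	c.1987T>A	p.Y663N	de_novo	+5	+3	mild		false
7	c.1991A>T	p.D664V	nk	+3.8	+3.2	moderate		false
8	c.2044G>A	p.A682T	de_novo	+4.2	+1.8	mild	Neuroblastoma ALL	false
9	c.2050C>T	p.R684C	de_novo	+2.9	nk	mild		false
10	c.2050C>T	p.R684C	nk	+3.5	+1.5	nk		true
11	c.2050C>T	p.R684C	de_novo	+3	+2.6	mild		false
12	c.2050C>T	p.R684C	nk	+5.6	+1.7	mild		false
13	c.2084C>T	p.S695L	de_novo	+5	nk	mild		false
14	c.2199C>G	p.Y733X	de_novo	+7.6	+2.7	no		true
15	c.2196-15_2196-2delTTCCTGTTGTTTCA		nk	+4.6	nk	nk		false
16	c.2204_2211dupAGGCTGAT		de_novo	+4.6	+2.2	moderate		true
17	c.2230_2232dupATC		nk	+3.4	+1.7	mild		false
18	c.2222A>G	p.Y741C	de_novo	+5.3	+2	no		false
19	c.2233G>A	p.E745K	nk	+3.5	+1.4	mild	Lymphoma	false
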