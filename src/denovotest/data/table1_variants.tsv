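# De novo BCL11A variants of the 11 reported individuals (coding positions are
# 1-based on the XL-isoform CDS, HGVS c. notation).
gene	position	ref	alt	consequence	individual	hgvs_c
BCL11A	139	A	C	missense	1	c.139A>C
BCL11A	143	G	T	missense	2	c.143G>T
BCL11A	198	C	A	missense	3	c.198C>A
BCL11A	529	C	T	nonsense	4	c.529C>T
BCL11A	2035	.	.	frameshift	5	c.2035_2037delinsC
BCL11A	1545	.	.	frameshift	6	c.1545delinsGGCTTC
BCL11A	1775	.	.	frameshift	7	c.1775_1776insTGGCTCAGCGG
BCL11A	154	C	T	nonsense	8	c.154C>T
BCL11A	193	G	T	nonsense	9	c.193G>T
BCL11A	1325	.	.	frameshift	10	c.1325_1325del
BCL11A	792	.	.	frameshift	11	c.792_793insC
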