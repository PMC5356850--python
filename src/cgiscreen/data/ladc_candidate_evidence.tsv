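# Published qRT-PCR evidence matrix for the nine genes at the top ten
# hypermethylated CpG islands of the stage-I lung adenocarcinoma discovery
# cohort. Fractions are k/n cells; a parenthesized fraction is an
# extended-panel annotation; "-" means not evaluable (very low normal
# expression).
gene	gene_context	normal_expression	tumor	cell	restore
DPP6	exon1	Yes	8/11	14/14	1/3
DDX25	exon1	Very low	-	-	-
ZNF577	exon1	Yes	6/11	10/14	0/3
FEZF2	gene_body	Very low	-	-	-
PEAR1	exon1	Yes	5/11	14/14	0/3
MEIS2	gene_body	Yes	4/11	3/14	1/3
TRIM58	exon1	Yes	10/11 (36/37)	10/14	3/3
C12orf42	gene_body	Very low	-	-	-
PTPRN2	gene_body	Yes	3/11	7/14	2/3
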