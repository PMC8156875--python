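# HML7 proviral loci colocalized with cellular genes: locus and strand,
# overlapping gene and strand, intronic/exonic call and sense/antisense
# orientation of the provirus relative to the gene.
locus	locus_strand	gene	gene_strand	overlap_class	orientation
1q43	+	PLD5	-	intronic	antisense
2q31.1	-	MYO3B	+	intronic	antisense
3q23	+	GK5	-	intronic	antisense
3q26.1	+	LINC01322	+	intronic	sense
4q25	-	LRIT3	+	intronic	antisense
5q22.3	-	KCNN2	+	intronic	antisense
6p12.3	-	GLYATL3	+	intronic	antisense
7q21.12	-	RUNDC3B	+	intronic	antisense
7q36.2	-	DPP6	+	intronic	antisense
15q24.3	+	SCAPER	-	intronic	antisense
Xq22.3	-	IL1RAPL2	+	intronic	antisense
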