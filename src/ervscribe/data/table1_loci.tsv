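# HML7 proviral loci in GRCh38/hg38: cytogenetic locus, strand, 1-based
# inclusive coordinates, estimated integration age (My; "-" = withheld,
# unreliable), oldest common ancestor (oca) with note, centromere-region
# flag, structural class, and the study that first reported the locus.
# oca_note: solo_converted = orthologue converted into a solitary LTR during
# primate speciation; missing_intermediate = orthologue absent from an
# intermediate species on the lineage.
locus	chrom	strand	start	end	age_My	oca	oca_note	region_flag	structure	first_reported
1q43	chr1	+	242457056	242460436	22.9	orangutan		other	defective	retrotector_screen
2q11.2	chr2	+	101237831	101245098	32.3	rhesus		pericentromeric	defective	retrotector_screen
2q31.1	chr2	-	170615659	170619450	24.3	gibbon		other	defective	blat_extension
3q11.2	chr3	+	94647178	94651193	46.9	gibbon		pericentromeric	defective	retrotector_screen
3q23	chr3	+	142206726	142207843	29.9	gibbon		other	defective	blat_extension
3q26.1	chr3	+	165546697	165548895	37.0	gibbon		other	defective	blat_extension
4q25	chr4	-	109855914	109859920	27.9	gibbon		other	defective	retrotector_screen
4q32.1	chr4	-	160255828	160257162	22.0	gibbon		other	defective	blat_extension
5p13.2	chr5	-	34460957	34468537	29.8	rhesus	solo_converted	other	defective	retrotector_screen
5q22.3	chr5	-	114142954	114150230	29.3	gibbon		other	defective	retrotector_screen
6p12.3	chr6	-	49501277	49508842	29.3	rhesus	solo_converted	other	defective	retrotector_screen
6q22.31	chr6	+	121042084	121049347	26.6	gibbon		other	defective	retrotector_screen
7q21.12	chr7	-	87732402	87733417	40.0	gibbon		other	defective	blat_extension
7q36.2	chr7	-	153843398	153844485	31.0	gibbon		other	defective	blat_extension
11p12	chr11	-	43161738	43168627	18.1	orangutan	solo_converted_gorilla	other	defective	retrotector_screen
11q14.3	chr11	-	92943568	92950131	26.4	gibbon		other	defective	retrotector_screen
12q12	chr12	+	38122838	38130125	36.4	gorilla		pericentromeric	defective	retrotector_screen
15q24.3	chr15	+	76639167	76641589	24.3	gibbon		other	defective	blat_extension
19q13.2	chr19	-	42712688	42713786	30.5	gibbon		other	defective	blat_extension
Xq11.1	chrX	-	62707600	62717099	-	gorilla	missing_intermediate	centromeric	complete	retrotector_screen
Xq22.3	chrX	-	105666188	105669044	22.0	gibbon		other	defective	blat_extension
Yq11.221	chrY	-	15973344	15982688	38.2	gorilla	solo_converted	other	near_complete	retrotector_screen
Yp11.2	chrY	-	7952560	7961873	38.2	chimp		other	complete	retrotector_screen
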