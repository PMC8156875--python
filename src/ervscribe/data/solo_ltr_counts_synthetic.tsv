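# Per-chromosome counts of HML7 elements.  Provirus counts are derived from
# the proviral locus table.  Solitary-LTR counts: chrX (17), chr15 (0) and
# chr20 (0) are fixed by the published per-chromosome statements; the
# remaining 143 of the 160 solitary LTRs are a SYNTHETIC length-proportional
# interpolation (largest-remainder rounding) standing in for the
# unpublished appendix coordinate list.
chrom	proviruses	solo_ltrs
chr1	1	13
chr2	2	13
chr3	3	10
chr4	2	10
chr5	2	9
chr6	2	9
chr7	2	8
chr8	0	7
chr9	0	7
chr10	0	7
chr11	2	7
chr12	1	7
chr13	0	6
chr14	0	6
chr15	1	0
chr16	0	5
chr17	0	4
chr18	0	4
chr19	1	3
chr20	0	0
chr21	0	2
chr22	0	3
chrX	2	17
chrY	2	3
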