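name	chrom	start	end	coordinate_convention	assembly	gene_strand
RUNX1_intron5	chr21	36200001	36224800	1-closed	hg19	-
SNRPD3_TSS_region	chr22	21000000	21010000	0-half-open	hg19	+
genefree_chr1	chr1	84000000	84025000	0-half-open	hg19	.
BCR_gene_MBCR	chr22	23520000	23527500	0-half-open	hg19	+
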