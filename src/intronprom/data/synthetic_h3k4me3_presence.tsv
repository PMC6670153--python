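cell_type	RUNX1_intron5|I	RUNX1_intron5|II	RUNX1_intron5|III	RUNX1_intron5|IV	RUNX1_intron5|V	RUNX1_intron5|VI	RUNX1_intron5|VII	RUNX1_intron5|VIII	RUNX1_intron5|IX	RUNX1_intron5|X	SNRPD3_TSS_region|I	SNRPD3_TSS_region|II	SNRPD3_TSS_region|III	SNRPD3_TSS_region|IV	genefree_chr1|I	genefree_chr1|II	genefree_chr1|III	genefree_chr1|IV	genefree_chr1|V	genefree_chr1|VI	genefree_chr1|VII	genefree_chr1|VIII	genefree_chr1|IX	genefree_chr1|X	BCR_gene_MBCR|I	BCR_gene_MBCR|II	BCR_gene_MBCR|III
HKCT000	0	0	0	0	0	1	1	0	0	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT001	0	0	0	0	0	1	1	0	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT002	0	0	0	0	0	1	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT003	0	0	0	0	0	1	0	0	1	1	1	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT004	0	0	0	0	0	0	1	1	0	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT005	0	0	0	0	0	1	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT006	0	0	0	0	0	1	0	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT007	0	0	1	0	0	1	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT008	0	0	0	1	0	1	0	0	1	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT009	0	0	0	0	1	1	0	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT010	0	0	0	0	0	1	0	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	1	0	0
HKCT011	1	0	0	0	0	0	0	0	1	1	1	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT012	0	1	0	0	1	1	0	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	1	0
HKCT013	0	0	0	0	0	1	1	1	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT014	0	0	0	1	0	1	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	1	0
HKCT015	0	0	0	0	0	1	0	0	1	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	1	1
HKCT016	0	0	0	0	1	1	0	1	1	0	0	1	1	1	0	0	0	0	0	0	0	0	0	0	1	0	0
HKCT017	0	0	0	0	0	1	0	0	1	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT018	0	1	0	0	0	0	1	0	0	1	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT019	0	0	0	0	0	1	0	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT020	0	0	0	0	0	1	0	0	1	1	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0	1	0
HKCT021	0	0	0	0	0	1	0	1	1	0	0	1	1	1	0	0	0	1	0	0	0	0	0	0	0	0	0
HKCT022	0	0	0	0	1	1	1	0	1	1	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT023	0	0	0	0	0	1	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT024	0	0	0	0	0	1	0	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	1	0
HKCT025	0	0	0	0	0	0	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT026	1	0	0	0	0	1	1	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT027	0	0	0	1	0	1	0	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT028	0	0	0	0	0	0	0	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT029	0	0	0	0	0	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT030	0	0	0	0	0	0	1	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT031	0	0	0	0	0	0	0	0	1	0	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT032	1	0	0	0	0	1	0	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT033	0	0	0	0	0	0	0	0	0	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT034	0	0	0	0	0	1	0	1	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT035	0	0	0	0	0	1	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT036	0	0	1	0	0	1	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT037	0	0	1	0	0	1	0	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT038	0	0	0	0	1	1	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT039	0	0	0	0	0	0	0	0	0	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT040	1	0	0	1	0	0	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT041	0	0	0	0	0	1	0	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT042	0	0	0	0	0	1	0	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	1
HKCT043	0	0	1	0	0	1	0	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT044	0	0	0	0	0	1	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT045	0	0	0	0	1	1	1	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT046	0	0	0	0	0	0	0	0	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	1	0	0
HKCT047	0	0	1	0	1	1	0	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT048	0	0	0	0	0	1	0	1	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT049	0	0	0	0	0	1	0	1	1	1	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
HKCT050	0	1	0	0	0	0	0	0	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
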