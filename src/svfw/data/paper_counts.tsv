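name	count	source
cancer_total	10034	results:headline
germline_total	5518	results:fig1a
somatic_total	4516	results:fig1a
unique_total	14719	results:headline
blood_only_total	4685	results:fig1a
germline_multisample	3059	results:fig2
somatic_multirecurrent	284	results:fig2
intragenic	5031	results:fig4a
gene_desert	3942	results:fig4a
intergenic	1061	results:fig4a
intergenic_somatic	677	results:fig4b
intergenic_germline	384	results:fig4b
promoter_total	398	results:fig5a
alt_5utr_total	45	results:fig5a
alt_3utr_total	74	results:fig5a
coding_fusion_total	52	results:fig5a
coding_fusion_in_frame	20	results:fig5a
coding_fusion_out_of_frame	32	results:fig5a
in_frame_somatic	17	results:fig5a
five_prime_truncated_total	208	results:rnaseq
uncharacterized_total	284	results:rnaseq
intragenic_intronic	4744	results:fig5b
intragenic_exonic	287	results:fig5b
exonic_noncoding	138	results:fig5b
exonic_5utr	17	results:fig5b
exonic_3utr	64	results:fig5b
exonic_cds	68	results:fig5b
fusions_rnaseq_eligible	663	results:rnaseq
fusions_expressed	103	results:rnaseq
germline_fusions_eligible	158	table1
germline_fusions_expressed	30	table1
somatic_fusions_eligible	505	table1
somatic_fusions_expressed	73	table1
coding_fusion_somatic	45	table1
coding_fusion_expressed	8	table1
five_prime_truncated_expressed	39	results:rnaseq
uncharacterized_expressed	47	results:rnaseq
alt_5utr_rnaseq_eligible	45	results:rnaseq
alt_5utr_expressed	2	results:rnaseq
alt_3utr_rnaseq_eligible	74	results:rnaseq
alt_3utr_expressed	7	results:rnaseq
microarray_eligible	517	results:microarray
microarray_somatic	249	results:microarray
microarray_germline	268	results:microarray
differential_somatic	42	table1
differential_germline	25	table1
differential_total	67	results:microarray
differential_up	31	results:microarray
differential_down	36	results:microarray
translocation_somatic_dna	398	table2
translocation_somatic_expressed	57	table2
translocation_germline_dna	125	table2
translocation_germline_expressed	26	table2
somatic_expressed_total	115	table2
germline_expressed_total	53	table2
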