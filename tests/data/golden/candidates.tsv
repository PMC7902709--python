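orf_id	species	annotation_status	description	subject_accession	genome	raw_score	e_value	percent_identity	cazy_family	cofactor	bio_reps_7d	total_peptides_7d	bio_reps_14d	total_peptides_14d	bio_reps_21d	total_peptides_21d	peak_total_peptides
contig_1:+1:16-298	synthetic sp.	annotated	Cupredoxin	KAF0000001.1		518.0	2e-150	81.2	AA1_3	Cu	4/4	24	4/4	40	4/4	18	40
contig_2:-2:24-321	synthetic sp.	annotated	GMC oxidoreductase	KAF0000003.1		1131.0	0.0	79.0	AA3	FAD	4/4	6	4/4	12	4/4	30	30
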