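orf_id	species	annotation_status	description	subject_accession	genome	raw_score	e_value	percent_identity	cazy_family	cofactor	bio_reps_7d	total_peptides_7d	bio_reps_14d	total_peptides_14d	bio_reps_21d	total_peptides_21d	peak_total_peptides
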