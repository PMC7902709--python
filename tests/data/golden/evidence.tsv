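orf_id	species	time_point	bio_reps	total_peptides	distinct_peptides	unique_peptides
contig_1:+1:16-298	synthetic sp.	7	4/4	24	7	24
contig_1:+1:16-298	synthetic sp.	14	4/4	40	7	40
contig_1:+1:16-298	synthetic sp.	21	4/4	18	5	18
contig_2:-2:24-321	synthetic sp.	7	4/4	6	6	6
contig_2:-2:24-321	synthetic sp.	14	4/4	12	10	12
contig_2:-2:24-321	synthetic sp.	21	4/4	30	15	30
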