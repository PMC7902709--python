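orf_id	species	time_point	bio_reps	total_peptides
OAL06359.1	Stagonospora sp.	7	8/8	61
OAL06359.1	Stagonospora sp.	14	4/4	49
OAL06359.1	Stagonospora sp.	21	2/2	39
OAL02734.1	Stagonospora sp.	7	8/8	41
OAL02734.1	Stagonospora sp.	14	3/4	26
OAL06112.1	Stagonospora sp.	7	6/8	26
OAL06112.1	Stagonospora sp.	14	4/4	38
OAL06112.1	Stagonospora sp.	21	2/2	21
OAK94057.1	Stagonospora sp.	14	3/4	9
OAK99381.1	Stagonospora sp.	7	1/8	7
OAK99381.1	Stagonospora sp.	21	2/2	11
OAL03573.1	Stagonospora sp.	14	1/4	3
OAL03573.1	Stagonospora sp.	21	2/2	8
OAK93932.1	Stagonospora sp.	14	1/4	3
OAK93932.1	Stagonospora sp.	21	2/2	12
OAK94822.1	Stagonospora sp.	21	1/2	5
OAL06123.1	Stagonospora sp.	21	1/2	4
OAK96127.1	Stagonospora sp.	21	1/2	3
OAL54547.1	Pyrenochaeta sp.	14	4/4	8
OAL53386.1	Pyrenochaeta sp.	21	2/3	10
OAL43510.1	Pyrenochaeta sp.	14	2/4	4
OAL43510.1	Pyrenochaeta sp.	21	1/3	3
OAL51393.1	Pyrenochaeta sp.	14	1/4	2
OAL49332.1	Pyrenochaeta sp.	14	1/4	2
XP_018032780.1	P. sporulosum	7	4/4	52
XP_018032780.1	P. sporulosum	14	4/4	33
XP_018032780.1	P. sporulosum	21	3/4	23
XP_018030874.1	P. sporulosum	7	3/4	7
XP_018030874.1	P. sporulosum	14	4/4	26
XP_018030874.1	P. sporulosum	21	4/4	17
XP_018033536.1	P. sporulosum	7	4/4	21
XP_018035449.1	P. sporulosum	7	4/4	18
XP_018035114.1	P. sporulosum	7	1/4	2
XP_018035504.1	P. sporulosum	7	1/4	2
XP_018033970.1	P. sporulosum	21	1/4	2
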