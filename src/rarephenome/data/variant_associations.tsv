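disease	orpha	marker	gene	consequence	acmg_classification	reported	p_value	case_mac	n_cases	percent_affected	control_maf
Polycythemia vera	729	9:5073770_G/T	JAK2	missense	Pathogenic (PS3/PS4)	Yes	1.32e-114	51	370	47	1.71e-04
Chronic myeloproliferative disease	86830	9:5073770_G/T	JAK2	missense	Pathogenic (PS3/PS4)	Yes	2.40e-67	30	154	28	2.33e-04
Essential thrombocythemia	3318	9:5073770_G/T	JAK2	missense	Pathogenic (PS3/PS4)	Yes	2.91e-42	21	218	19	2.60e-04
Primary myelofibrosis	824	9:5073770_G/T	JAK2	missense	Pathogenic (PS3/PS4)	Yes	5.30e-40	16	52	15	2.75e-04
Immune thrombocytopenic purpura	3002	9:5073770_G/T	JAK2	missense	Pathogenic (PS3/PS4)	No	2.63e-18	11	368	10	2.90e-04
Chronic myelomonocytic leukemia	98823	17:76736877_G/A	SRSF2	missense	Likely pathogenic (PS4/PM1)	No	1.19e-13	4	32	27	3.29e-05
Essential thrombocythemia	3318	19:12943813_A/ATTGTC	CALR	frameshift	Pathogenic (PVS1/PS4)	No	2.82e-13	5	218	50	1.50e-05
Beta-thalassemia	848	11:5226774_G/A	HBB	stop_gained	Pathogenic (PVS1/PS4)	Yes	3.46e-12	3	12	33	1.79e-05
Congenital factor XI deficiency	329	4:186288589_T/G	F11	missense	Pathogenic (PS4/PM1/PM2/PP2/PP3)	No	3.41e-11	3	18	12	6.58e-05
B-cell chronic lymphocytic leukemia	67038	3:38141150_T/C	MYD88	stop_lost	Pathogenic (PS4/PM2/PM4/PP3/PP5)	Yes	2.42e-10	4	490	57	8.98e-06
Acute panmyelosis with myelofibrosis	86843	9:5073770_G/T	JAK2	missense	Pathogenic (PS3/PS4)	No	7.81e-10	3	8	3	3.14e-04
Immune thrombocytopenic purpura	3002	16:83907050_G/A	MLYCD	missense	Likely pathogenic (PS4/PM2)	No	7.60e-08	4	368	8	1.35e-04
Osteochondritis dissecans	2764	17:10505866_C/T	MYH1	missense	Likely pathogenic (PS4/PM1)	No	1.01e-07	3	56	3	2.84e-04
AA amyloidosis	85445	2:151727817_T/TGCTGGCTGTGCCAGA	NEB	disruptive_inframe_insertion	Likely pathogenic (PS4/PM4)	No	1.97e-07	3	24	1	7.56e-04
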