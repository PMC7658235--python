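# Clinicopathological features of the 23 MDS-EB patients treated with
# azacitidine before stem cell transplantation. Response codes: CR =
# complete remission, mCR = marrow complete remission (+/- hematologic
# improvement, HI), "primary DP to ..." = primary disease progression,
# SD-HI = stable disease without hematologic improvement. Mutations are
# from a targeted panel available for 8 patients (NA = not assayed,
# none = assayed, none detected). survival_months is follow-up time;
# status is died/alive at last follow-up.
patient	sex	age	who_subtype	bm_blast_pct	mutations	response	cycles	outcome	survival_months	status
1	M	63	MDS-EB-2	10	LAMB4	CR	3	post-SCT AML	19.6	died
2	M	68	MDS-EB-2	19	SF3B1	CR	9	secondary resistance and progression to AML	12.0	died
3	F	55	MDS-EB-1	8	NA	CR	4	post-SCT AML	24.2	died
4	M	65	MDS-EB-1	8	NA	CR	5	post-SCT relapse	29.1	died
5	F	59	MDS-EB-2	15	NA	CR	5	post-SCT relapse	40.1	alive
6	F	71	MDS-EB-1	7	NA	CR	6	secondary resistance	46.3	alive
7	M	71	MDS-EB-2	10	NA	CR	4	post-SCT remission	30.3	alive
8	M	66	MDS-EB-2	15	NRAS;TET2;ETV6;KRAS	mCR+HI-E/P	6	secondary resistance	17.2	died
9	M	55	MDS-EB-2	11	NA	mCR+HI-E	8	post-SCT remission	32.6	alive
10	M	75	MDS-EB-2	8	NA	mCR-HI-E	6	secondary resistance and progression to AML	21.8	died
11	M	53	MDS-EB-1	8	JAK2;ETV6	mCR-HI	2	post-SCT toxicity	6.2	died
12	F	41	MDS-EB-1	8	none	mCR-HI	2	post-SCT remission	71.5	alive
13	F	68	MDS-EB-2	15	NA	mCR-HI	2	brain hemorrhage	9.2	died
14	M	59	MDS-EB-2	17	TET2;ASXL1;RUNX1	mCR-HI	5	post-SCT toxicity	13.5	died
15	M	77	MDS-EB-1	6	NA	primary DP to AML	1	AML	1.1	died
16	M	73	MDS-EB-2	12	NA	primary DP to AML	2	AML	11.4	died
17	M	67	MDS-EB-1	9	NA	primary DP to AML	6	AML	7.6	died
18	F	38	MDS-EB-2	10	EZH2	primary DP to AML	2	AML	2.7	died
19	M	42	MDS-EB-2	10	NA	primary DP to AML	4	post-SCT remission	40.7	alive
20	M	52	MDS-EB-2	17	NRAS;EZH2	primary DP to AML	3	post-SCT relapse	21.4	died
21	M	71	MDS-EB-1	6	NA	primary DP to EB-2	2	AML	43.5	alive
22	M	62	MDS-EB-1	8	NA	primary DP to EB-2	6	post-SCT remission	42.3	alive
23	M	64	MDS-EB-2	19	NA	SD-HI	5	post-SCT AML	24.6	died
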