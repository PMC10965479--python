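dataset_id	population	sex	n_samples	data_kind	path	genes_in_module	enrichment_p
1	Hybrid mouse diversity panel	male	288	transcriptome		787	3.9e-7
2	Hybrid mouse diversity panel	male	227	transcriptome		165	1.9e-18
3	Hybrid mouse diversity panel	female	206	transcriptome		372	7.0e-15
4	Hybrid mouse diversity panel	male	78	transcriptome		85	5.2e-19
5	Diversity outbred	male	48	transcriptome		108	6.0e-26
6	Diversity outbred	female	50	transcriptome		68	2.8e-25
7	Diversity outbred	male	46	transcriptome		206	9.5e-18
8	Diversity outbred	female	48	transcriptome		642	7.0e-14
9	Diversity outbred	male	48	transcriptome		61	5.3e-13
10	Diversity outbred	female	50	transcriptome		77	8.8e-23
11	Diversity outbred	male	46	transcriptome		57	7.5e-16
12	Diversity outbred	female	48	transcriptome		35	5.8e-27
13	Hybrid mouse diversity population	male	115	transcriptome		189	3.7e-35
14	F2: C57BL/6J-ApoE-/- and C3H/HeJ-ApoE-/-	female	142	transcriptome		200	8.3e-19
15	F2: C57BL/6J-ApoE-/- and C3H/HeJ-ApoE-/-	male	142	transcriptome		50	4.9e-30
16	Hybrid mouse diversity population	female	96	transcriptome		138	1.4e-18
17	Hybrid mouse diversity population	male	101	transcriptome		73	4.6e-22
18	Hybrid mouse diversity population	male	295	transcriptome		13	1.2e-9
19	F2: CAST/EiJ and C57BL/6J	male	173	transcriptome		41	5.5e-3
20	F2: CAST/EiJ and C57BL/6J	female	249	transcriptome		12	2.1e-2
21	Hybrid mouse diversity population	male	97	transcriptome		88	2.3e-4
22	Hybrid mouse diversity population	male	99	transcriptome		69	3.3e-41
23	Hybrid mouse diversity population	male	96	transcriptome		146	3.24e-29
24	F2: C57BL/6J and DBA/2J	female	111	transcriptome		44	2.1e-4
25	F2: C57BL/6J Lep-ob/ob and BTBR-T+ Itpr3tf/J Lep-ob/ob	female	254	transcriptome		35	3.0e-24
26	F2: C57BL/6J Lep-ob/ob and BTBR-T+ Itpr3tf/J Lep-ob/ob	male	220	transcriptome		28	3.8e-28
27	F2: C57BL/6J and C3H/HeJ	female	77	transcriptome		132	1.5e-10
28	F2: C57BL/6J and C3H/HeJ	male	82	transcriptome		18	8.6e-15
29	BXD family	male	25	transcriptome		36	1.2e-13
30	BXD family	male	40	transcriptome		186	7.1e-26
31	BXD family	male	40	transcriptome		300	2.7e-17
32	BXD family	male	53	transcriptome		14	3.2e-2
33	BXD family	male	36	transcriptome		33	3.0e-3
34	BXD family	male	41	transcriptome		32	5.6e-15
35	BXD family	female	41	transcriptome		58	9.3e-17
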