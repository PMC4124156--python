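rank	res_i	aa_i	region_i	res_j	aa_j	region_j	d_model	d_3wo6	status_printed
1	354	TRP	TM2						indel
2	355	GLY	TM2						indel
3	356	PHE	TM2						indel
4	356	PHE	TM2	533	ARG	c-term			topology_violation
5	358	ILE	TM2	512	GLY	Loop5-6	9.1	6.1	retained
6	359	ILE	TM2	519	VAL	TM6	6.5	5.2	retained
7	359	ILE	TM2	515	LEU	TM6	8.5	7.9	retained
8	359	ILE	TM2						indel
9	361	ILE	TM2	436	LEU	TM3	7.9	8.2	retained
10	362	THR	TM2	371	PRO	TM2			intrahelical
11	363	PHE	TM2	523	VAL	TM6	5.2	6.1	retained
12	367	GLY	TM2	523	VAL	TM6	6.0	8.2	retained
13	369	MET	TM2	432	ILE	TM3	9.9	8.4	retained
14	372	LEU	Loop2-3	510	PRO	Loop5-6			topology_violation
15	379	SER	Loop2-3	425	PRO	TM3	10.2	9.9	retained
16	386	LEU	Loop2-3	417	VAL	Loop2-3	7.5	7.1	retained
17	386	LEU	Loop2-3	411	LEU	Loop2-3	6.2	6.1	retained
18	388	PRO	Loop2-3	429	GLN	TM3			topology_violation
19	389	LYS	Loop2-3	414	ALA	Loop2-3	10.5	9.8	retained
20	389	LYS	Loop2-3	415	GLU	Loop2-3	11.2	10.0	retained
21	390	ILE	Loop2-3	408	MET	Loop2-3	6.8	6.2	retained
22	393	MET	Loop2-3	404	ILE	Loop2-3	7.9	7.4	retained
23	393	MET	Loop2-3	411	LEU	Loop2-3	8.2	7.7	retained
24	394	ARG	Loop2-3	404	ILE	Loop2-3	8.5	8.1	retained
25	396	ARG	Loop2-3	407	GLU	Loop2-3	8.9	8.4	retained
26	423	CYS	TM3	528	GLN	TM6	16.2	20.9	retained
27	425	PRO	TM3	499	PRO	TM5	10.2	20.5	retained
28	433	PHE	TM3	524	THR	TM6	11.0	14.9	retained
29	436	LEU	TM3	512	GLY	Loop5-6	7.6	8.3	retained
30	437	TYR	TM3	513	LEU	Loop5-6	9.8	6.4	retained
31	454	TRP	Loop3-4	462	ASP	Loop3-4	6.6	7.0	retained
32	454	TRP	Loop3-4	468	PRO	TM4	16.0	11.5	retained
33	454	TRP	Loop3-4	511	SER	Loop5-6	9.8	8.3	retained
34	455	ILE	Loop3-4	467	LEU	TM4	9.8	10.1	retained
35	455	ILE	Loop3-4	466	ILE	TM4	11.0	8.0	retained
36	462	ASP	Loop3-4	468	PRO	TM4	12.5	6.8	retained
37	462	ASP	Loop3-4	511	SER	Loop5-6	11.1	4.2	retained
38	465	TYR	TM4	507	LEU	TM5	10.4	8.7	retained
39	467	LEU	TM4	515	LEU	TM6	11.6	6.6	retained
40	468	PRO	TM4	513	LEU	TM6	14.5	8.8	retained
41	470	LEU	TM4	518	ILE	TM6	6.3	5.4	retained
42	471	MET	TM4	502	PHE	TM5	8.8	4.9	retained
43	472	GLY	TM4	503	THR	TM5	6.7	5.3	retained
44	472	GLY	TM4	479	GLN	TM4			intrahelical
45	474	THR	TM4	521	ASN	TM6	4.7	3.7	retained
46	474	THR	TM4	525	ILE	TM6	6.7	7.8	retained
47	478	ILE	TM4	525	ILE	TM6	9.0	5.0	retained
48	485	THR	Loop4-5						indel
49	506	PHE	TM5	514	VAL	TM6	14.4	4.2	retained
50	512	GLY	Loop5-6	532	GLN	TM6			topology_violation
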