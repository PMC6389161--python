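# 16 classical per-residue physicochemical scales (hydrophobicity, energy,
# burial, size, flexibility, secondary-structure propensity); values as
# commonly tabulated in the literature. Residue columns are alphabetical
# one-letter codes.
name	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
KYTE_DOOLITTLE	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
HOPP_WOODS	-0.5	-1	3	3	-2.5	0	-0.5	-1.8	3	-1.8	-1.3	0.2	0	0.2	3	0.3	-0.4	-1.5	-3.4	-2.3
EISENBERG_CONS	0.62	0.29	-0.9	-0.74	1.19	0.48	-0.4	1.38	-1.5	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
FAUCHERE_PLISKA	0.31	1.54	-0.77	-0.64	1.79	0	0.13	1.8	-0.99	1.7	1.23	-0.6	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
JANIN_BURIED	0.3	0.9	-0.6	-0.7	0.5	0.3	-0.1	0.7	-1.8	0.5	0.4	-0.5	-0.3	-0.7	-1.4	-0.1	-0.2	0.6	0.3	-0.4
ENGELMAN_GES	1.6	2	-9.2	-8.2	3.7	1	-3	3.1	-8.8	2.8	3.4	-4.8	-0.2	-4.1	-12.3	0.6	1.2	2.6	1.9	-0.7
WIMLEY_WHITE_IF	0.17	-0.24	1.23	2.02	-1.13	0.01	0.17	-0.31	0.99	-0.56	-0.23	0.42	0.45	0.58	0.81	0.13	0.14	0.07	-1.85	-0.94
ROSE_BURIAL	0.74	0.91	0.62	0.62	0.88	0.72	0.78	0.88	0.52	0.85	0.85	0.63	0.64	0.62	0.64	0.66	0.7	0.86	0.85	0.76
CORNETTE_PRIFT	0.2	4.1	-3.1	-1.8	4.4	0	0.5	4.8	-3.1	5.7	4.2	-0.5	-2.2	-2.8	1.4	-0.5	-1.9	4.7	1	3.2
HESSA_TM	0.11	-0.13	3.49	2.68	-0.32	0.74	2.06	-0.6	2.71	-0.55	-0.1	2.05	2.23	2.36	2.58	0.84	0.52	-0.31	0.3	0.68
RESIDUE_MASS	71.08	103.14	115.09	129.12	147.18	57.05	137.14	113.16	128.17	113.16	131.19	114.1	97.12	128.13	156.19	87.08	101.1	99.13	186.21	163.18
RESIDUE_VOLUME	88.6	108.5	111.1	138.4	189.9	60.1	153.2	166.7	168.6	166.7	162.9	114.1	112.7	143.8	173.4	89	116.1	140	227.8	193.6
AVG_FLEXIBILITY	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.42
GRANTHAM_POLARITY	8.1	5.5	13	12.3	5.2	9	10.4	5.2	11.3	4.9	5.7	11.6	8	10.5	10.5	9.2	8.6	5.9	5.4	6.2
CHOU_FASMAN_HELIX	1.42	0.7	1.01	1.51	1.13	0.57	1	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
CHOU_FASMAN_SHEET	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.6	0.74	1.3	1.05	0.89	0.55	1.1	0.93	0.75	1.19	1.7	1.37	1.47
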