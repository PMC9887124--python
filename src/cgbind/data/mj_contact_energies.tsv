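# Miyazawa-Jernigan inter-residue contact energies e_ij (kcal/mol),
# symmetric 20x20; rows/columns in one-letter-code order given in the header.
res	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-2.72	-3.57	-1.70	-1.51	-4.81	-2.31	-2.41	-4.58	-1.31	-4.91	-3.94	-1.84	-2.03	-1.89	-1.83	-2.01	-2.32	-4.04	-3.82	-3.36
C	-3.57	-5.44	-2.41	-2.27	-5.80	-3.16	-3.60	-5.50	-1.95	-5.83	-4.99	-2.59	-3.07	-2.85	-2.57	-2.86	-3.11	-4.96	-4.95	-4.16
D	-1.70	-2.41	-1.21	-1.02	-3.48	-1.59	-2.32	-3.17	-1.68	-3.40	-2.57	-1.68	-1.33	-1.46	-2.29	-1.63	-1.80	-2.48	-2.84	-2.76
E	-1.51	-2.27	-1.02	-0.91	-3.56	-1.22	-2.15	-3.27	-1.80	-3.59	-2.89	-1.51	-1.26	-1.42	-2.27	-1.48	-1.74	-2.67	-2.99	-2.79
F	-4.81	-5.80	-3.48	-3.56	-7.26	-4.13	-4.77	-6.84	-3.36	-7.28	-6.56	-3.75	-4.25	-4.10	-3.98	-4.02	-4.28	-6.29	-6.16	-5.66
G	-2.31	-3.16	-1.59	-1.22	-4.13	-2.24	-2.15	-3.78	-1.15	-4.16	-3.39	-1.74	-1.87	-1.66	-1.72	-1.82	-2.08	-3.38	-3.42	-3.01
H	-2.41	-3.60	-2.32	-2.15	-4.77	-2.15	-3.05	-4.14	-1.35	-4.54	-3.98	-2.08	-2.25	-1.98	-2.16	-2.11	-2.42	-3.58	-3.98	-3.52
I	-4.58	-5.50	-3.17	-3.27	-6.84	-3.78	-4.14	-6.54	-3.01	-7.04	-6.02	-3.24	-3.76	-3.67	-3.63	-3.52	-4.03	-6.05	-5.78	-5.25
K	-1.31	-1.95	-1.68	-1.80	-3.36	-1.15	-1.35	-3.01	-0.12	-3.37	-2.48	-1.21	-0.97	-1.29	-0.59	-1.05	-1.31	-2.49	-2.69	-2.60
L	-4.91	-5.83	-3.40	-3.59	-7.28	-4.16	-4.54	-7.04	-3.37	-7.37	-6.41	-3.74	-4.20	-4.04	-4.03	-3.92	-4.34	-6.48	-6.14	-5.67
M	-3.94	-4.99	-2.57	-2.89	-6.56	-3.39	-3.98	-6.02	-2.48	-6.41	-5.46	-2.95	-3.45	-3.30	-3.12	-3.03	-3.51	-5.32	-5.55	-4.91
N	-1.84	-2.59	-1.68	-1.51	-3.75	-1.74	-2.08	-3.24	-1.21	-3.74	-2.95	-1.68	-1.53	-1.71	-1.64	-1.58	-1.88	-2.83	-3.07	-2.76
P	-2.03	-3.07	-1.33	-1.26	-4.25	-1.87	-2.25	-3.76	-0.97	-4.20	-3.45	-1.53	-1.75	-1.73	-1.70	-1.57	-1.90	-3.32	-3.73	-3.19
Q	-1.89	-2.85	-1.46	-1.42	-4.10	-1.66	-1.98	-3.67	-1.29	-4.04	-3.30	-1.71	-1.73	-1.54	-1.80	-1.49	-1.90	-3.07	-3.11	-2.97
R	-1.83	-2.57	-2.29	-2.27	-3.98	-1.72	-2.16	-3.63	-0.59	-4.03	-3.12	-1.64	-1.70	-1.80	-1.55	-1.62	-1.90	-3.07	-3.41	-3.16
S	-2.01	-2.86	-1.63	-1.48	-4.02	-1.82	-2.11	-3.52	-1.05	-3.92	-3.03	-1.58	-1.57	-1.49	-1.62	-1.67	-1.96	-3.05	-2.99	-2.78
T	-2.32	-3.11	-1.80	-1.74	-4.28	-2.08	-2.42	-4.03	-1.31	-4.34	-3.51	-1.88	-1.90	-1.90	-1.90	-1.96	-2.12	-3.46	-3.22	-3.01
V	-4.04	-4.96	-2.48	-2.67	-6.29	-3.38	-3.58	-6.05	-2.49	-6.48	-5.32	-2.83	-3.32	-3.07	-3.07	-3.05	-3.46	-5.52	-5.18	-4.62
W	-3.82	-4.95	-2.84	-2.99	-6.16	-3.42	-3.98	-5.78	-2.69	-6.14	-5.55	-3.07	-3.73	-3.11	-3.41	-2.99	-3.22	-5.18	-5.06	-4.66
Y	-3.36	-4.16	-2.76	-2.79	-5.66	-3.01	-3.52	-5.25	-2.60	-5.67	-4.91	-2.76	-3.19	-2.97	-3.16	-2.78	-3.01	-4.62	-4.66	-4.17
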