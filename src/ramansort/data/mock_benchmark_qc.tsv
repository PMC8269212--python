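# Per-cell sequencing-QC outcomes for the four-species mock-community sorting
# benchmark (three sorting criteria x three biological replicates; references
# Hp = H. pylori, Se = S. elongatus, Sc = S. cerevisiae, Ec = E. coli).
# NC rows are empty-droplet negative controls.
experiment_id	sample_id	mapped_Hp	mapped_Se	mapped_Sc	mapped_Ec	hit_no_genomes_pct	taxonomy_bin	completeness_pct	contaminant_bound_pct	consistent_with_sort	is_negative_control
A-1	A-1-Se1	0.13	99.05	0.00	0.08	0.78	Se	99.66	16.67	yes	no
A-1	A-1-Se3	0.07	91.68	0.02	0.05	8.25	Se	91.38	4.17	yes	no
A-1	A-1-Se5	0.14	97.86	0.00	0.12	2.12	Se	99.29	4.17	yes	no
A-1	A-1-Hp2	99.76	0.06	0.03	0.04	0.10	Hp	46.74	6.46	yes	no
A-1	A-1-Hp4	96.69	0.22	0.00	0.35	3.09	Hp	62.40	12.36	yes	no
A-1	A-1-Sc3	0.01	0.09	21.48	0.03	78.34	Sc	57.70	9.95	yes	no
A-1	A-1-Sc4	0.60	0.84	84.10	0.59	14.59	Sc	30.14	8.43	yes	no
A-1	A-1-Ec2	0.04	0.02	0.00	86.01	13.73	Ec	43.36	1.72	yes	no
A-1	A-1-NC	0.03	0.10	0.00	0.00	99.53				yes	yes
A-2	A-2-Se2	0.21	82.55	0.08	0.13	16.81	Se	94.90	4.04	yes	no
A-2	A-2-Se3	12.83	61.22	0.01	0.05	25.85	Se	56.60	4.17	yes	no
A-2	A-2-Se5	0.09	87.70	0.00	0.12	12.11	Se	61.90	4.17	yes	no
A-2	A-2-Hp1	98.58	0.26	0.49	0.50	0.79	Hp	89.30	1.72	yes	no
A-2	A-2-Hp5	96.64	0.08	0.28	0.42	0.42	Hp	93.20	27.56	yes	no
A-2	A-2-Sc1	0.00	0.00	99.79	0.00	0.18	Sc	92.90	0.00	yes	no
A-2	A-2-Sc3	0.01	0.00	97.86	0.00	2.06	Sc	93.60	5.42	yes	no
A-2	A-2-Ec3	1.97	0.30	0.06	82.54	14.55	Ec	86.00	18.43	yes	no
A-2	A-2-Ec4	1.76	0.14	0.04	83.50	14.02	Ec	88.20	0.31	yes	no
A-3	A-3-Se1	0.01	77.73	0.18	0.04	21.96	Se	65.80	4.17	yes	no
A-3	A-3-Hp2	96.39	0.09	0.90	0.13	2.50	Hp	94.20	13.79	yes	no
A-3	A-3-Hp4	82.81	2.11	0.07	4.60	16.13	Hp	56.30	14.25	yes	no
A-3	A-3-Hp5	97.80	0.75	0.22	0.83	1.93	Hp	79.70	0.16	yes	no
A-3	A-3-Sc2	0.47	0.01	97.10	0.02	2.29	Sc	86.30	4.17	yes	no
A-3	A-3-Sc3	0.85	0.00	98.63	0.00	0.43	Sc	68.40	13.03	yes	no
A-3	A-3-Sc4	0.05	0.00	97.85	0.00	2.05	Sc	89.60	7.02	yes	no
A-3	A-3-Sc5	0.19	0.00	96.85	0.00	2.87	Sc	89.00	5.26	yes	no
A-3	A-3-Ec5	0.32	0.26	0.06	91.22	8.09	Ec	76.60	7.44	yes	no
A-3	A-3-NC	0.00	0.02	0.06	0.26	96.71				yes	yes
B-1	B-1-Ec2	0.29	0.28	0.00	80.11	19.23	Ec	80.09	3.45	yes	no
B-1	B-1-Ec4	1.33	0.73	0.08	66.35	33.55	Ec	25.91	10.34	yes	no
B-1	B-1-Ec7	0.00	0.01	0.79	19.13	79.75	Ec	20.81	4.67	yes	no
B-1	B-1-Ec10	0.20	0.14	0.00	94.41	1.29	Ec	18.37	0.96	yes	no
B-1	B-1-NC	0.00	0.00	0.00	0.00	99.95				yes	yes
B-2	B-2-Ec3	0.28	0.42	0.01	82.25	16.64	Ec	90.90	57.07	yes	no
B-2	B-2-Ec5	0.33	0.61	0.02	72.95	26.09	Ec	84.90	36.07	yes	no
B-2	B-2-Ec8	0.19	0.46	0.02	76.24	22.05	Ec	46.50	30.83	yes	no
B-2	B-2-NC	0.00	0.02	0.05	0.06	99.41				yes	yes
B-3	B-3-Ec1	0.49	0.73	0.04	79.26	19.54	Ec	90.60	44.26	yes	no
B-3	B-3-Ec8	0.27	0.27	0.00	88.91	10.23	Ec	90.00	19.65	yes	no
C-1	C-1-Se1	0.03	17.49	0.14	0.17	82.12	Se	53.80	10.64	yes	no
C-1	C-1-Se5	0.15	96.61	0.07	0.18	3.09	Se	99.69	10.10	yes	no
C-1	C-1-Se8	0.14	95.04	0.06	0.19	4.63	Se	99.73	9.64	yes	no
C-1	C-1-Se10	0.15	89.16	0.00	0.12	10.69	Se	99.72	7.86	yes	no
C-1	C-1-NC	0.00	0.00	0.00	0.00	98.23				yes	yes
C-2	C-2-Se6	0.63	80.63	0.00	13.51	5.23	Se	99.70	12.73	yes	no
C-2	C-2-Se7	17.61	75.14	0.00	0.10	7.06	Se	93.60	16.67	yes	no
C-2	C-2-Se10	0.15	96.72	0.00	1.29	2.08	Se	98.40	8.07	yes	no
C-2	C-2-NC	0.00	0.00	1.15	0.01	74.40				yes	yes
C-3	C-3-Se2	0.31	98.27	0.06	0.14	1.27	Se	96.40	8.33	yes	no
C-3	C-3-Se5	0.09	96.24	0.04	0.09	3.66	Se	97.10	4.17	yes	no
C-3	C-3-Se9	0.08	69.78	0.05	0.01	29.95	Se	86.40	10.34	yes	no
C-3	C-3-NC	0.00	0.00	0.78	0.24	95.47				yes	yes
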