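outcome	gene	probe	probe_chr	probe_bp	topSNP	topSNP_chr	topSNP_bp	effect_allele	other_allele	freq	b_eqtl	se_eqtl	p_eqtl	b_gwas	se_gwas	p_gwas	b_smr	se_smr	p_smr	p_smr_multi	p_heidi	nsnp_heidi
er_positive	P4HA1	P4HA1	10	74811853	rs6480668	10	74849326	G	A	0.24	0.183	0.016	3.35E-32	-0.045	0.015	2.49E-03	-0.247	0.084	3.30E-03	2.02E-04	3.72E-01	8
er_positive	SLC12A2	SLC12A2	5	127472419	rs17764730	5	127357526	T	C	0.21	-0.186	0.009	3.20E-86	0.029	0.009	6.96E-04	-0.158	0.048	8.67E-04	8.87E-02	1.23E-01	20
er_positive	KCNJ11	KCNJ11	11	17409142	rs2074310	11	17421886	T	C	0.26	0.157	0.012	4.37E-38	-0.016	0.008	4.20E-02	-0.099	0.050	4.53E-02	5.34E-01	4.33E-01	20
er_positive	PDE1B	PDE1B	12	54958078	rs1874308	12	54954356	A	T	0.39	0.429	0.009	0.00E+00	0.030	0.008	3.38E-04	0.070	0.019	3.28E-04	1.55E-02	2.37E-01	14
er_negative	SLC12A2	SLC12A2	5	127472419	rs17764730	5	127357526	T	C	0.21	-0.186	0.009	3.20E-86	0.037	0.013	5.13E-03	-0.200	0.072	5.75E-03	2.21E-01	7.17E-01	20
luminal_a	P4HA1	P4HA1	10	74811853	rs6480668	10	74849326	G	A	0.24	0.183	0.016	3.35E-32	-0.044	0.016	6.35E-03	-0.238	0.090	7.84E-03	8.79E-04	9.37E-01	8
luminal_a	PDE1B	PDE1B	12	54958078	rs1874308	12	54954356	A	T	0.39	0.429	0.009	0.00E+00	0.023	0.009	9.75E-03	0.053	0.020	9.86E-03	1.66E-02	5.67E-01	14
luminal_a	CA12	CA12	15	63643968	rs12909041	15	63743677	A	C	0.36	0.039	0.010	1.14E-04	-0.024	0.010	1.51E-02	-0.632	0.307	3.97E-02	5.73E-01	5.06E-01	6
luminal_a	SLC12A2	SLC12A2	5	127472419	rs17764730	5	127357526	T	C	0.21	-0.186	0.009	3.20E-86	0.019	0.009	4.35E-02	-0.101	0.050	4.46E-02	8.34E-01	9.57E-01	20
luminal_b	P4HA1	P4HA1	10	74811853	rs6480668	10	74849326	G	A	0.24	0.183	0.016	3.35E-32	-0.093	0.037	1.11E-02	-0.506	0.204	1.31E-02	3.38E-02	9.98E-01	8
luminal_b	GPR35	GPR35	2	241557762	rs2975788	2	241571858	G	A	0.43	0.293	0.009	6.23E-259	-0.044	0.019	2.02E-02	-0.151	0.065	2.05E-02	4.70E-01	1.21E-02	20
luminal_b	SLC12A2	SLC12A2	5	127472419	rs17764730	5	127357526	T	C	0.21	-0.186	0.009	3.20E-86	0.044	0.020	3.24E-02	-0.236	0.111	3.34E-02	2.45E-02	1.73E-02	20
luminal_b	CACNA1D	CACNA1D	3	53687586	rs983063	3	53735766	G	A	0.29	-0.085	0.009	2.00E-22	0.042	0.020	3.17E-02	-0.499	0.238	3.59E-02	1.59E-01	6.17E-01	20
luminal_b	CA12	CA12	15	63643968	rs12909041	15	63743677	A	C	0.36	0.039	0.010	1.14E-04	-0.056	0.023	1.29E-02	-1.457	0.697	3.66E-02	9.74E-01	8.70E-01	6
luminal_b	ATP1A1	ATP1A1	1	116934086	rs6704439	1	116867616	A	C	0.30	0.041	0.009	4.39E-06	0.050	0.022	2.10E-02	1.216	0.590	3.92E-02	3.08E-01	9.63E-01	20
luminal_b	NR3C1	NR3C1	5	142736286	rs4912908	5	142791133	G	A	0.17	0.073	0.010	1.07E-13	0.047	0.023	3.76E-02	0.649	0.324	4.53E-02	1.80E-01	3.31E-01	14
luminal_b_her2_neg	SLC12A2	SLC12A2	5	127472419	rs17764730	5	127357526	T	C	0.21	-0.186	0.009	3.20E-86	0.054	0.017	1.82E-03	-0.292	0.095	2.08E-03	4.36E-02	6.53E-01	20
luminal_b_her2_neg	SCNN1D	SCNN1D	1	1221612	rs6662635	1	1220425	G	A	0.08	-0.475	0.044	4.76E-27	-0.206	0.080	1.03E-02	0.434	0.174	1.26E-02	7.41E-01	3.35E-01	20
her2_enriched	KCNJ11	KCNJ11	11	17409142	rs2074310	11	17421886	T	C	0.26	0.157	0.012	4.37E-38	-0.041	0.027	1.28E-01	-0.258	0.171	1.31E-01	5.89E-01	6.21E-01	20
her2_enriched	ACE	ACE	17	61576813	rs4277405	17	61548918	C	T	0.35	0.075	0.009	1.59E-17	0.069	0.026	7.99E-03	0.918	0.363	1.13E-02	7.14E-01	1.93E-01	20
triple_negative	AOC1	AOC1	7	150540153	rs7806458	7	150476888	G	A	0.28	0.669	0.008	0.00E+00	-0.031	0.016	4.97E-02	-0.046	0.024	4.97E-02	2.68E-01	9.62E-01	20
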