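outcome	gene	probe	probe_chr	probe_bp	topSNP	topSNP_chr	topSNP_bp	effect_allele	other_allele	freq	b_eqtl	se_eqtl	p_eqtl	b_gwas	se_gwas	p_gwas	b_smr	se_smr	p_smr	p_smr_multi	p_heidi	nsnp_heidi
overall	SLC12A2	SLC12A2	5	127472419	rs17764730	5	127357526	T	C	0.21	-0.186	0.009	3.2E-86	0.028	0.007	7.57E-05	-0.150	0.039	1.05E-04	2.58E-02	1.56E-01	20
overall	P4HA1	P4HA1	10	74811853	rs6480668	10	74849326	G	A	0.24	0.183	0.016	3.35E-32	-0.032	0.012	7.83E-03	-0.176	0.068	9.47E-03	1.30E-03	4.98E-01	8
overall	CA12	CA12	15	63643968	rs12909041	15	63743677	A	C	0.36	0.039	0.010	1.14E-04	-0.026	0.008	6.88E-04	-0.670	0.263	1.08E-02	7.12E-01	5.35E-01	5
overall	PDE1B	PDE1B	12	54958078	rs10747699	12	54955324	T	C	0.39	0.406	0.009	0.00E+00	0.017	0.007	1.31E-02	0.041	0.017	1.32E-02	2.02E-03	3.63E-01	3
overall	KCNJ11	KCNJ11	11	17409142	rs2074310	11	17421886	T	C	0.26	0.157	0.012	4.37E-38	-0.015	0.006	1.99E-02	-0.092	0.040	2.20E-02	4.89E-01	8.06E-02	20
overall	NR3C1	NR3C1	5	142736286	rs4912908	5	142791133	G	A	0.17	0.073	0.010	1.07E-13	0.016	0.008	4.67E-02	0.221	0.115	5.47E-02	3.22E-03	2.81E-02	15
overall	ATP1A1	ATP1A1	1	116934086	rs6704439	1	116867616	A	C	0.30	0.041	0.009	4.39E-06	0.015	0.008	5.47E-02	0.363	0.205	7.64E-02	1.74E-01	8.28E-01	20
overall	KCNJ2	KCNJ2	17	68170501	rs9890133	17	68169005	G	A	0.15	-0.256	0.012	8.02E-94	-0.015	0.010	1.12E-01	0.060	0.038	1.13E-01	7.26E-01	9.60E-01	20
overall	SLC12A1	SLC12A1	15	48540068	rs964611	15	48597514	A	C	0.15	1.664	0.009	0.00E+00	-0.012	0.009	1.78E-01	-0.007	0.005	1.78E-01	1.21E-01	9.86E-01	20
overall	CACNA2D2	CACNA2D2	3	50470954	rs6226081	3	50474624	A	G	0.05	-0.142	0.013	8.98E-29	-0.013	0.010	2.03E-01	0.089	0.070	2.06E-01	1.36E-03	3.88E-01	20
overall	AHR	AHR	7	17362011	rs17643734	7	17162882	G	A	0.03	0.478	0.016	3.7E-184	0.015	0.013	2.70E-01	0.030	0.028	2.71E-01	1.18E-02	9.83E-01	20
overall	ACE	ACE	17	61576813	rs4277405	17	61548918	C	T	0.35	0.075	0.009	1.59E-17	0.006	0.006	3.18E-01	0.083	0.084	3.21E-01	9.76E-01	9.97E-01	20
overall	AQP1	AQP1	7	30929070	rs2075574	7	30950744	T	C	0.37	0.113	0.013	3.77E-19	-0.008	0.009	3.50E-01	-0.073	0.078	3.53E-01	9.92E-01	7.67E-01	5
overall	SLC9A1	SLC9A1	1	27459389	rs6683016	1	27493194	T	C	0.28	-0.096	0.008	9E-31	-0.004	0.006	5.37E-01	0.041	0.066	5.38E-01	4.95E-02	7.61E-02	20
overall	AOC1	AOC1	7	150540153	rs7806458	7	150476888	G	A	0.28	0.669	0.008	0.00E+00	-0.003	0.006	6.20E-01	-0.005	0.009	6.20E-01	4.21E-02	7.63E-01	20
overall	CACNA1H	CACNA1H	16	1237506	rs117177120	16	1238875	G	T	0.02	0.372	0.024	4.41E-54	0.004	0.016	7.82E-01	0.012	0.042	7.82E-01	9.90E-01	4.21E-01	20
overall	SLC16A1	SLC16A1	1	113477052	rs1049434	1	113456546	A	T	0.32	0.125	0.008	9.29E-54	0.002	0.006	8.02E-01	0.013	0.050	8.02E-01	7.22E-01	4.06E-01	20
overall	GPR35	GPR35	2	241557762	rs2975788	2	241571858	G	A	0.43	0.293	0.009	6.2E-259	0.002	0.007	8.10E-01	0.005	0.022	8.10E-01	8.83E-01	5.79E-01	20
overall	CACNA1D	CACNA1D	3	53687586	rs983063	3	53735766	G	A	0.29	-0.085	0.009	2E-22	-0.001	0.007	9.19E-01	0.008	0.080	9.19E-01	9.83E-02	3.50E-01	20
overall	ADRB2	ADRB2	5	148207176	rs2082395	5	148200600	A	G	0.35	0.126	0.008	6.31E-56	-0.001	0.006	9.37E-01	-0.004	0.050	9.37E-01	1.02E-01	7.18E-01	4
overall	CA4	CA4	17	58237778	rs34820870	17	58244021	G	T	0.16	-0.462	0.021	6.1E-110	0.001	0.016	9.50E-01	-0.002	0.036	9.50E-01	4.38E-02	9.89E-01	20
overall	JUN	JUN	1	59248125	rs2716140	1	59472397	C	A	0.39	-0.228	0.008	3.5E-177	0.000	0.007	9.57E-01	0.002	0.030	9.57E-01	3.69E-01	9.06E-01	20
overall	SCNN1D	SCNN1D	1	1221612	rs6662635	1	1220425	G	A	0.08	-0.475	0.044	4.76E-27	-0.001	0.031	9.80E-01	0.002	0.064	9.80E-01	7.26E-01	9.46E-01	20
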