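id	gene	chrom	pos	ea	nea	freq_ea	levene_p_stage1	levene_p_stage2	beta_gxe_aosw	ci_lo_aosw	ci_hi_aosw	p_gxe_aosw	beta_gxe_avmse	ci_lo_avmse	ci_hi_avmse	p_gxe_avmse
rs634990	GJD2	15	35006073	C	T	0.492	1.18E-17	1.37E-09	-0.569	-0.765	-0.373	1.32E-08	-0.071	-0.121	-0.021	5.63E-03
rs11602008	LRRC4C	11	40149305	T	A	0.17	9.31E-16	1.57E-14	-0.477	-0.739	-0.214	3.68E-04	-0.049	-0.117	0.019	1.54E-01
rs12193446	LAMA2	6	129820038	A	G	0.904	1.32E-15	3.08E-28	-0.887	-1.219	-0.554	1.74E-07	-0.130	-0.215	-0.044	2.91E-03
rs1550094	PRSS56	2	233385396	G	A	0.304	9.03E-11	3.83E-06	-0.290	-0.503	-0.077	7.69E-03	-0.046	-0.100	0.009	1.02E-01
rs9911460	FAAP100	17	79538841	T	A	0.477	5.68E-10	1.29E-39	-0.036	-0.234	0.161	7.19E-01	-0.044	-0.095	0.006	8.55E-02
rs7744813	KCNQ5	6	73643289	A	C	0.588	1.59E-09	7.34E-10	-0.375	-0.577	-0.173	2.76E-04	-0.038	-0.090	0.014	1.49E-01
rs7188859	RBFOX1	16	7460426	C	T	0.365	6.91E-09	9.59E-17	-0.417	-0.623	-0.211	7.49E-05	-0.067	-0.120	-0.014	1.38E-02
rs10917958	NMNAT1P2	1	164214985	T	C	0.234	2.06E-08	1.40E-05	-0.131	-0.363	0.101	2.68E-01	0.021	-0.038	0.081	4.85E-01
rs368893443	ACTN2	13	100690003	AAGAG	A	0.454	3.07E-07	3.85E-08	0.087	-0.111	0.285	3.91E-01	-0.006	-0.057	0.045	8.27E-01
rs6979354	SP4	7	21417963	T	C	0.555	1.71E-06	1.40E-02	0.092	-0.111	0.294	3.76E-01	-0.030	-0.082	0.022	2.54E-01
rs12450368	CDRT15	17	14138507	C	T	0.409	4.03E-06	3.42E-04	-0.236	-0.448	-0.024	2.94E-02	-0.015	-0.070	0.039	5.86E-01
rs13181905	EBF1	5	158492279	A	C	0.436	6.28E-06	3.51E-02	-0.220	-0.421	-0.019	3.21E-02	-0.032	-0.083	0.020	2.31E-01
rs11033093	SLC1A2	11	35381495	G	C	0.103	7.18E-06	9.98E-01	-0.232	-0.555	0.091	1.59E-01	0.027	-0.056	0.110	5.21E-01
rs2980823	TCIM	8	40148843	G	T	0.582	9.54E-06	4.83E-01	0.026	-0.174	0.226	8.00E-01	0.029	-0.022	0.081	2.67E-01
rs36005291	TOX	8	60179048	CA	C	0.655	1.24E-05	2.20E-06	-0.630	-0.839	-0.422	3.21E-09	-0.024	-0.078	0.029	3.78E-01
rs418092	GPX6	6	28533946	T	C	0.333	1.30E-05	3.60E-02	0.062	-0.147	0.270	5.63E-01	0.012	-0.042	0.065	6.72E-01
rs2607006	SGF29	16	28576017	C	T	0.414	1.48E-05	8.89E-01	-0.153	-0.359	0.053	1.46E-01	-0.025	-0.078	0.027	3.48E-01
rs9518096	GGACT	13	101223109	C	T	0.481	1.74E-05	3.00E-06	0.073	-0.124	0.270	4.66E-01	-0.012	-0.063	0.038	6.30E-01
rs77483535	THAP6	4	76312573	T	C	0.302	2.48E-05	3.67E-01	0.059	-0.163	0.281	6.01E-01	-0.008	-0.064	0.049	7.94E-01
rs435555	SLC52A1	17	4947305	T	C	0.556	2.83E-05	1.03E-03	-0.023	-0.222	0.175	8.18E-01	-0.022	-0.072	0.029	4.03E-01
rs34720604	KLHL1	13	70190188	T	TA	0.729	3.40E-05	5.62E-01	0.245	0.023	0.467	3.08E-02	-0.006	-0.063	0.052	8.50E-01
rs869422	ZMAT4	8	40723970	A	G	0.794	3.67E-05	2.20E-12	-0.217	-0.460	0.026	8.03E-02	-0.100	-0.163	-0.038	1.65E-03
rs1868289	GRIN2A	16	10215813	T	G	0.678	3.84E-05	2.79E-02	-0.175	-0.386	0.036	1.04E-01	-0.026	-0.080	0.029	3.56E-01
rs7678123	CFAP299	4	81372405	C	G	0.284	4.25E-05	5.89E-06	-0.152	-0.370	0.066	1.73E-01	-0.017	-0.074	0.039	5.42E-01
rs10637890	CDKN3	14	54779523	T	TCT	0.375	4.57E-05	6.71E-01	-0.058	-0.263	0.147	5.81E-01	-0.013	-0.066	0.040	6.25E-01
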