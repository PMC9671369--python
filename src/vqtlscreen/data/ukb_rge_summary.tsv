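id	gene	ea	nea	freq_ea_uniedu_yes	freq_ea_uniedu_no	odds_ratio	or_ci_lo	or_ci_hi	p
rs36005291	TOX	CA	C	0.656	0.654	0.992	0.979	1.004	0.195
rs634990	GJD2	C	T	0.492	0.492	1.002	0.990	1.015	0.691
rs12193446	LAMA2	A	G	0.905	0.904	0.991	0.971	1.012	0.392
rs7188859	RBFOX1	C	T	0.363	0.366	0.988	0.976	1.001	0.067
rs7744813	KCNQ5	A	C	0.587	0.588	1.003	0.991	1.016	0.606
rs11602008	LRRC4C	T	A	0.171	0.169	1.017	1.001	1.034	0.034
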