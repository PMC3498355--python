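ligand	pKa	Cw_M	IC50_uM	IC50_sd_uM	IC50_censored	Vmol_A3	dG_diss_kcal	dG_solv_anion_kcal	dG_bind_neutral_kcal	dG_bind_anion_kcal	RMSF_A	RMSD_A
Bt	8.56	1.96e-1	2000	nan	1	127.1	59.5	-59.9	6.3	5.7	0.47	2.99
4-BrBt	7.08	3.87e-3	119	10	0	151.1	56.7	-53.3	7.0	6.5	0.47	0.76
5-BrBt	7.55	2.77e-3	26	3	0	151.3	58.1	-50.7	6.8	6.5	0.55	0.57
4,5-Br2Bt	6.49	4.99e-4	10.6	0.9	0	172.1	54.3	-46.8	7.9	7.1	0.42	0.26
4,6-Br2Bt	6.38	2.34e-4	10.0	2.2	0	174.7	54.2	-45.5	7.5	7.1	0.60	0.76
4,7-Br2Bt	5.84	1.98e-3	72	11	0	174.9	53.4	-48.0	7.2	6.9	0.40	0.81
5,6-Br2Bt	6.93	2.31e-4	0.56	0.02	0	172.4	55.8	-44.4	7.7	7.1	0.46	0.87
4,5,6-Br3Bt	5.91	6.23e-5	0.38	0.02	0	192.8	52.3	-40.9	8.6	7.7	0.45	0.13
4,5,7-Br3Bt	5.38	1.04e-3	5.8	0.9	0	195.9	52.2	-41.9	8.1	7.8	0.46	0.64
TBBt	4.78	2.18e-4	0.27	0.07	0	213.0	49.7	-38.0	8.9	8.4	0.52	0.71
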