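# Selected (breeding) QTL hotspots: genetic CI on the consensus map plus physical
# CIs on the Svevo and Chinese Spring (CS) assemblies. pve is the mean PVE over
# the member MTAs. A single-position genetic CI is stored with start == end.
hotspot_id	chromosome	ci_cm_start	ci_cm_end	ci_svevo_start_mb	ci_svevo_end_mb	ci_cs_start_mb	ci_cs_end_mb	n_mta	pve	traits
1	1A	1	7	1.1	7.6	1.3	7.6	11	0.07	Color,DEE,DOE,FIRM,GPS,GS,PPO,SV,WTS,YPC
4	1B	2	5	6.3	8.2	6.0	9.6	7	0.08	CWT,FIRM,DOE,GPC,GS,MIXO,SV
5	1B	15	16	19.5	19.6	22.2	22.9	8	0.07	CWT,DEE,DOE,DOTE,GPS,GS,MIXO,SV
10	1B	117	118	628.2	632.4	633.3	637.8	3	0.13	b*,GPC,YPC
15	2A	119	119	586.6	596.9	593.5	603.6	3	0.19	L*,YPC
26	2B	182	184	775.7	777.5	787.8	789.6	7	0.10	DEE,dif,GPC,GLUT,PRLOSS,VIT,WG
31	3B	5	6	5.8	15.2	6.2	13.9	5	0.06	CLOSS,CWT,FIRM,WTS,YPC
33	3B	87	88	503.1	512.0	491.4	507.0	7	0.06	Color,CWT,dif,FIRM,GS,MIXO,YPC
35	3B	145	146	749.3	752.6	739.2	742.1	3	0.12	HMW-GS/LMW-GS,YPC
47	4B	19	21	19.1	22.1	19.7	22.6	6	0.14	CLOSS,DOE,GPS,PLOSS,VIT,YPC
49	4B	29	30	26.6	27.0	28.1	28.5	3	0.36	PLOSS,YPC
51	4B	39	41	59.1	75.6	60.5	77.0	5	0.12	b*,TW,YPC
52	4B	59	60	473.1	492.7	469.0	488.7	8	0.11	GPC,PLOSS,PRLOSS,WG,YPC
57	5A	111	115	489.4	503.6	526.4	540.6	7	0.19	CWT,FIRM,GLI,Gli+Glu,WTS
64	6A	1	4	4.7	7.4	6.6	9.5	5	0.04	Color,GL,GLUT,IP,YPC
73	6A	125	129	603.5	615.3	609.1	616.3	6	0.05	AX,CLOSS,Color,dif
79	7A	59	61	60.9	63.6	63.1	65.5	7	0.09	GPC,SPROT,VIT,WG,YPC
81	7A	102	102	148.3	159.4	151.4	161.7	5	0.06	DEE,DOTE,GPC,GPS,YPC
85	7A	179	184	691.0	699.0	697.0	705.1	10	0.12	AX,Color,CWT,dif,FIRM,WTS,YPC
92	7B	204	206	714.7	716.2	734.3	741.2	5	0.09	IP,YPC
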