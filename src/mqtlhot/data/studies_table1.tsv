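# Summary of the ten GWAS studies pooled in the meta-analysis (published 2015-2020).
study_id	panel	size	n_mta	traits
S01	Agrogen	104	19	AX
S02	Agrogen	230	7	BG
S03	Durum collection (7 subspecies)	124	6	YPC
S04	Worldwide elite durum wheat	93	20	YPC
S05	Mediterranean landraces	172	14	GPC,GS,TW,YPC
S06	Cultivars and inbred lines (1997-2014)	243	163	CLOSS,Color,CWT,dif,FIRM,GLUT,GPC,GS,MIXO,PPO,SASH,SEXT,SPROT,SV,TEXT,VIT,WG,WTS,YPC
S07	Italian durum breeding lines	79	44	Gli,Gli+Glu,HMW/LMW,IP,TPT
S08	Ethiopian durum wheat	192	20	a*,b*,L*,GL,GW
S09	Canadian durum breeding lines	192	80	DEE,DOE,DOTE,GPC,GS,PLOSS,PRLOSS,YPC
S10	Canadian durum wheat collection	169	22	PLOSS,YPC
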