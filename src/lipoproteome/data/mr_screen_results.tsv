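exposure	protein	beta	se	pvalue
LPA	Ig K chain V-I region HK102-like	-0.0030	0.0008	0.0003
LPA	ICOS	-0.0025	0.0007	0.0007
LPA	LRP1B	-0.0029	0.0009	0.0007
LPA	Fas. soluble	-0.0025	0.0007	0.0007
LPA	HGD	0.0024	0.0007	0.0012
LPA	Fas, soluble	-0.0024	0.0007	0.0014
LPA	Trefoil factor 2	-0.0023	0.0007	0.0016
LPA	NMT1	0.0023	0.0007	0.0017
LPA	SC5A8	-0.0027	0.0009	0.0020
LPA	Fragile histidine triad protein	0.0023	0.0007	0.0021
LPA	SAPL1	0.0023	0.0007	0.0023
LPA	CDON	-0.0023	0.0008	0.0027
LPA	SYAC	0.0022	0.0007	0.0028
LPA	BAG3	-0.0024	0.0008	0.0028
LPA	ERAB	0.0024	0.0008	0.0029
LPA	TNF SR-II	-0.0022	0.0007	0.0029
LPA	Glutathione S-transferase Pi	0.0022	0.0008	0.0030
LPA	IL-12 RB2	-0.0022	0.0007	0.0032
LDL	PKB B	0.4349	0.0642	1.22e-11
LDL	CN093	0.4163	0.0757	3.88e-8
LDL	GPR110	0.4928	0.0898	4.04e-8
LDL	CEI	0.9195	0.1774	2.18e-7
LDL	SELS	0.5541	0.1080	2.89e-7
LDL	PCDBA	0.3396	0.0665	3.25e-7
LDL	DCK	0.4210	0.0826	3.47e-7
LDL	MPIP2	0.3240	0.0641	4.30e-7
LDL	LRP1B	0.5355	0.1074	6.11e-7
LDL	PSG5	0.3503	0.0719	1.12e-6
LDL	QORL1	0.3625	0.0755	1.60e-6
LDL	Cytochrome P450 3A4	0.4206	0.0885	2.01e-6
LDL	SC5A8	0.4386	0.0928	2.26e-6
LDL	UBP21	0.3271	0.0698	2.76e-6
LDL	NPTX2	0.3677	0.0790	3.20e-6
LDL	Cardiotrophin-1	0.8167	0.1801	5.76e-6
LDL	P5I11	0.3508	0.0790	9.07e-6
LDL	DEAF1	0.2974	0.0687	1.49e-5
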