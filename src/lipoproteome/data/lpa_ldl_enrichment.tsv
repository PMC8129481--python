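gene	protein	discovery_ratio	discovery_p	replication_ratio	replication_p
SERPING1	Plasma protease C1 inhibitor	234.8	2.19e-9	108.1	1.65e-5
PI16	Peptidase inhibitor 16	158.8	5.19e-9	17.2	0.02
ITIH2	Inter-alpha-trypsin inhibitor heavy chain H2	151.5	1.30e-7	17.8	1.14e-5
PON1	Serum paraoxonase/arylesterase 1	103.4	2.59e-8	35.0	2.39e-6
ITIH3	Inter-alpha-trypsin inhibitor heavy chain H3	87.8	3.69e-6	30.2	9.39e-4
ITIH1	Inter-alpha-trypsin inhibitor heavy chain H1	79.3	6.57e-7	16.0	2.74e-5
PODXL	Podocalyxin	77.9	5.74e-8	150.9	6.53e-10
CD44	CD44 antigen	69.3	2.22e-7	253.0	5.80e-11
CP	Ceruloplasmin	67.5	2.31e-5	614.7	1.16e-5
PTPRG	Receptor-type tyrosine-protein phosphatase gamma	61.8	1.32e-7	62.1	1.40e-8
VTN	Vitronectin	35.7	4.50e-6	9.8	6.71e-6
PCSK9	Proprotein convertase subtilisin/kexin type 9	32.3	7.94e-7	6.7	1.66e-2
IGFALS	Insulin-like growth factor-binding protein complex acid labile subunit	31.4	1.31e-5	6.5	2.93e-5
VCAM1	Vascular cell adhesion protein 1	21.9	9.62e-6	5.0	1.61e-2
TTR	Transthyretin	10.7	2.89e-6	16.2	1.89e-7
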