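table	patient	gene	aa_change	blast_diagnosis	var_diagnosis	wt_diagnosis	pct_diagnosis	blast_relapse	var_relapse	wt_relapse	pct_relapse	var_cr	wt_cr	pct_cr	discordant_cell
table3	ALL001	OXTR	p.Ser377Ile	90	23	18	62.3	92	32	33	53.5	0	83	0	none
table3	ALL001	TBX21	p.Phe292LeufsX12	90	25	41	42.1	92	46	57	48.5	0	114	0	none
table3	ALL001	STEAP3	p.Pro210Leu	90	5	10	37	92	17	15	57.7	0	73	0	none
table3	ALL001	SLURP1	p.Cys25Phe	90	10	25	31.7	92	22	36	41.2	0	118	0	none
table3	ALL001	CSPP1	p.Leu1103Pro	90	30	41	46.9	92	21	26	48.6	0	97	0	none
table3	ALL001	KDM6A	p.Asn855ArgfsX20	90	35	81	33.5	92	44	66	43.5	0	70	0	none
table3	ALL001	PTPN21	p.Pro525Ala	90	10	13	48.3	92	21	20	55.7	0	107	0	none
table3	ALL001	PTPN21	p.Ala659Thr	90	12	13	53.3	92	20	21	53.0	0	29	0	none
table3	ALL002	CREBBP	p.Arg1446His	95	37	50	44.8	33	21	107	49.7	0	81	0	none
table3	ALL002	RGS11	p.Arg409Arg	95	14	23	39.8	33	21	120	45.1	0	23	0	none
table3	ALL002	USP54	p.Arg1417His	95	0	50	0	33	13	62	52.5	0	55	0	none
table3	ALL002	NCOR2	p.Ala2013Thr	95	0	37	0	33	7	26	64.8	0	22	0	relapse
table3	ALL002	NRF1	p.Lys226Ile	95	44	33	60.9	33	1	72	4.2	0	42	0	diagnosis
table3	ALL002	MARCKS	p.Ala15Thr	95	11	13	48.2	33	0	49	0	0	23	0	none
table3	ALL002	USP11	p.Ala739Thr	95	31	24	59.3	33	0	44	0	0	40	0	none
table3	ALL002	ELK1	p.Pro238Leu	95	21	31	42.5	33	0	47	0	0	42	0	none
table3	ALL002	MYC	p.Pro74Arg	95	10	5	70.2	33	0	37	0	0	31	0	none
table3	ALL003	USP54	p.Thr1044Ser	93	37	115	26.2	74	0	118	0	6	166	3.5	none
table3	ALL003	GABRA3	p.Ser60Gly	93	25	39	42	74	0	39	0	0	70	0	none
table3	ALL003	KRAS	p.Gly12Arg	93	39	85	33.8	74	0	138	0	0	107	0	none
table3	ALL003	SETD2	p.Lys2506_His2507insVal	93	61	57	55.6	74	0	83	0	6	107	5.3	none
table3	ALL003	MYH7	p.Leu1104Gln	93	0	73	0	74	26	38	54.9	0	65	0	none
table3	ALL003	NYNRIN	p.Thr652SerfsX50	93	0	24	0	74	33	44	57.9	0	37	0	none
table3	ALL003	ODZ1	unknown	93	0	54	0	74	19	37	45.8	0	60	0	none
table3	ALL003	ZIC3	p.Arg123His	93	0	39	0	74	10	14	56.3	0	34	0	none
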