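table	gene	patient	group	cohort	status	mutation_type	mutation_id	aa_change
table2	CREBBP	ALL002	relapsed	discovery	shared	nonsynonymous	c.4337G>A	p.Arg1446His
table2	CREBBP	ALL030	relapsed	extension	relapse_specific	nonsynonymous	c.5098C>A	p.Q1700K
table2	CREBBP	ALL056	relapsed	extension	shared	nonsynonymous	c.3710G>A	p.C1237Y
table2	CREBBP	ALL065	relapsed	extension	shared	nonsynonymous	c.4463C>T	p.P1488L
table2	KRAS	ALL003	relapsed	discovery	diagnosis_specific	nonsynonymous	c.34G>C	p.G12R
table2	KRAS	ALL064	relapsed	extension	shared	nonsynonymous	c.173C>T	p.T58I
table2	KRAS	ALL024	relapsed	extension	shared	nonsynonymous	c.38G>A	p.G13D
table2	PTPN21	ALL001	relapsed	discovery	shared	nonsynonymous	c.1573C>G	p.Pro525Ala
table2	PTPN21	ALL001	relapsed	discovery	shared	nonsynonymous	c.1975G>A	p.Ala659Thr
table2	PTPN21	ALL050	relapsed	extension	relapse_specific	nonsynonymous	c.1514C>A	p.P505Q
table2	KDM6A	ALL001	relapsed	discovery	shared	frameshift	c.2563_2564insG	p.Asn855Argfs*20
table2	KDM6A	ALL062	relapsed	extension	shared	inframe_indel	c.4031_4051delinsGGG	p.Val1344_Arg1351delinsGlyGly
table2	USP54	ALL002	relapsed	discovery	relapse_specific	nonsynonymous	c.3130A>T	p.Thr1044Ser
table2	USP54	ALL003	relapsed	discovery	diagnosis_specific	nonsynonymous	c.4250G>A	p.Arg1417His
table2	NR3C1	ALL051	relapsed	extension	relapse_specific	frameshift	c.431_431delinsAG	p.D144Efs*11
table2	NR3C1	ALL061	relapsed	extension	relapse_specific	stopgain	c.640C>T	p.Q214X
table2	MYC	ALL002	relapsed	discovery	diagnosis_specific	nonsynonymous	c.221C>G	p.Pro74Arg
table2	MYC	ALL037	relapsed	extension	relapse_specific	nonsynonymous	c.293G>A	p.R98Q
table2	MYC	ALLN018	non_relapsed	extension	diagnosis_only_nonrelapsed	nonsynonymous	c.223C>T	p.P75S
table2	TBX21	ALL001	relapsed	discovery	shared	frameshift	c.875_876insGG	p.Phe292Leufs*12
table2	TBX21	ALLN011	non_relapsed	extension	diagnosis_only_nonrelapsed	nonsynonymous	c.76G>C	p.A26P
table2	SETD2	ALL003	relapsed	discovery	diagnosis_specific	inframe_indel	c.7517_7518insGGT	p.Lys2506_His2507insVal
table2	SETD2	ALL024	relapsed	extension	shared	stopgain	c.5345G>A	p.W1782X
table2	SETD2	ALL024	relapsed	extension	shared	nonsynonymous	c.4808A>G	p.H1603R
table2	SETD2	ALL063	relapsed	extension	shared	nonsynonymous	c.4874G>A	p.R1625H
table2	SETD2	ALL063	relapsed	extension	shared	frameshift	c.1508_1509insTTCG	p.Glu503Aspfs*18
table2	SETD2	ALL066	relapsed	extension	relapse_specific	frameshift	c.7199_7201delinsCT	p.Asp2400Alafs*11
table2	PAX5	ALLN019	non_relapsed	extension	diagnosis_only_nonrelapsed	nonsynonymous	c.77T>G	p.V26G
table2	PAX5	ALLN024	non_relapsed	extension	diagnosis_only_nonrelapsed	nonsynonymous	c.191G>T	p.C64F
table2	PAX5	ALL026	relapsed	extension	shared	nonsynonymous	c.239C>G	p.P80R
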