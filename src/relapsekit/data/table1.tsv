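table	patient	gene	status
table1	ALL001	OXTR	shared
table1	ALL001	TBX21	shared
table1	ALL001	STEAP3	shared
table1	ALL001	SLURP1	shared
table1	ALL001	CSPP1	shared
table1	ALL001	KDM6A	shared
table1	ALL001	PTPN21	shared
table1	ALL002	NRF1	diagnosis_specific
table1	ALL002	MARCKS	diagnosis_specific
table1	ALL002	USP11	diagnosis_specific
table1	ALL002	ELK1	diagnosis_specific
table1	ALL002	MYC	diagnosis_specific
table1	ALL002	CREBBP	shared
table1	ALL002	RGS11	shared
table1	ALL002	USP54	relapse_specific
table1	ALL002	NCOR2	relapse_specific
table1	ALL003	USP54	diagnosis_specific
table1	ALL003	GABRA3	diagnosis_specific
table1	ALL003	KRAS	diagnosis_specific
table1	ALL003	SETD2	diagnosis_specific
table1	ALL003	MYH7	relapse_specific
table1	ALL003	NYNRIN	relapse_specific
table1	ALL003	ODZ1	relapse_specific
table1	ALL003	ZIC3	relapse_specific
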