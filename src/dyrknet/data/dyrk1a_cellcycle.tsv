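#species
id	name	role	y_init	y_max	tau
DYRK1A	DYRK1A kinase	input	0	0.9	1
BMyb	B-Myb transcription factor	input	0	0.1	1
CDK2	cyclin-dependent kinase 2	input	0	0.8	1
pLIN52	LIN52 phosphorylated at S28	intermediate	0	1	1
DREAM	DREAM repressor complex	intermediate	0	1	1
CycD	cyclin D	intermediate	0	1	1
CycE	cyclin E	intermediate	0	1	1
CycE_CDK2	cyclin E/CDK2 complex	intermediate	0	1	1
RB1	active (hypophosphorylated) RB-1	intermediate	0	1	1
E2F1	E2F1 transcription factor	intermediate	0	1	1
E2F2	E2F2 transcription factor	intermediate	0	1	1
E2F3	E2F3 transcription factor	intermediate	0	1	1
DNA_replication	DNA replication program	output	0	1	1
#rules
rule	w	n	ec50
=> DYRK1A	1	1.4	0.5
=> BMyb	1	1.4	0.5
=> CDK2	1	1.4	0.5
DYRK1A => pLIN52	1	1.4	0.5
pLIN52 & !BMyb & !CycD => DREAM	1	1.4	0.5
!DYRK1A => CycD	1	1.4	0.5
=> CycE	0.18	1.4	0.5
E2F1 => CycE	1	1.4	0.5
E2F2 => CycE	1	1.4	0.5
E2F3 => CycE	1	1.4	0.5
CycE & CDK2 => CycE_CDK2	1	1.4	0.5
!CycD & !CycE_CDK2 => RB1	1	1.4	0.5
!RB1 & !DREAM => E2F1	1	1.4	0.5
!RB1 & !DREAM => E2F2	1	1.4	0.5
!RB1 & !DREAM => E2F3	1	1.4	0.5
E2F1 & E2F2 & E2F3 => DNA_replication	1	1.4	0.5
CycE_CDK2 => DNA_replication	1	1.4	0.5
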