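id	perturbation	readout	expected_direction	context	source
v1	KO:DYRK1A	DNA_replication	increase	cardiomyocyte	DYRK1A loss induces cardiomyocyte cell-cycle entry
v2	KO:DYRK1A	CycD	increase	cardiomyocyte	cyclin D rises on DYRK1A inhibition in cardiomyocytes
v3	OE:DYRK1A	DNA_replication	decrease	cardiomyocyte	DYRK1A overexpression decreases cardiomyocyte proliferation
v4	OE:DYRK1A	E2F1	decrease	cardiomyocyte	elevated DYRK1A dosage reduces E2F target transcription
v5	OE:CDK2	DNA_replication	increase	cardiomyocyte	CDK2 overexpression promotes DNA replication
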