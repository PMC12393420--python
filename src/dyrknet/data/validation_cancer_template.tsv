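# Template for the cancer-literature validation suite.
# Fill one row per curated experiment; perturbation grammar is
# KO:<species>[:<fraction>] or OE:<species>, multiple separated by ';'.
id	perturbation	readout	expected_direction	context	source
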