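gene	aa_index	source_label
rps14	27	Arabidopsis
rps14	50	Arabidopsis
accD	264	Arabidopsis
clpP1	187	Arabidopsis
rpoA	277	Arabidopsis
ndhD	128	Arabidopsis
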