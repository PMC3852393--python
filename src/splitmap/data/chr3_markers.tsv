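symbol	cM	cyto	phenotype_note
R	1.4	62A	Roughened: rough eye
D	40.7	70D	Dichaete: extended wings, missing alulae
Gl	41.4	70C	Glued: smaller rough eyes
Sb	58.2	89B	Stubble: short thick bristles on notum
H	69.5	92F	Hairless: missing postvertical bristles
Pr	90.0	98A	Prickly: short thin-tipped bristles on notum
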