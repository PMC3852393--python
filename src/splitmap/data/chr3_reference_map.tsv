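# Synthetic substitute reference table for cM<->cytology interpolation on
# Drosophila melanogaster chromosome 3, assembled from community-standard
# genetic map positions and cytological locations of classical loci.
symbol	cM	cyto
ru	0.0	61F
h	26.5	66D
D	40.7	70D
st	44.0	73A
p	48.0	85A
cu	50.0	86D
Sb	58.2	89B
sr	62.0	90E
gl	63.1	91A
e	70.7	93D
E(spl)	89.1	96F
ro	91.1	97D
ca	100.7	99B
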