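# The 24 third-chromosome deficiencies named in the bundled mapping table,
# with their reported cytological locations (deficiencies reported at two
# locations are merged into one span).
name	cyto_start	cyto_end
Df(3L)BSC362	61C	61C
Df(3L)Exel6105	64D	64D
Df(3L)Exel6112	66B	66B
Df(3L)BSC388	66B	66B
Df(3L)BSC673	67B	67D
Df(3L)ED4457	68A	68A
Df(3L)ED217	71B	71B
Df(3L)BSC774	72D	72D
Df(3L)ED4606	72D	72D
Df(3L)BSC775	75E	75E
Df(3L)ED229	76A	76D
Df(3L)ED5100	82D	82D
Df(3R)Tpl10	83E	83E
Df(3R)BSC466	85A	85A
Df(3R)BSC507	85D	85D
Df(3R)BSC486	87D	87D
Df(3R)Exel6178	90F	90F
Df(3R)ED5938	92A	92A
Df(3R)BSC677	93D	93F
Df(3R)BSC619	94E	94E
Df(3R)ED6187	95F	95F
Df(3R)Exel6203	96E	96E
Df(3R)BSC501	99A	99A
Df(3R)BSC503	99F	99F
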