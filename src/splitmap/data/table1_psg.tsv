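mutation	alleles	est_cM	est_cyto	df	actual_cyto
psg8	2	left of R	61A	Df(3L)BSC362	61C
psg28	1	left of R	61A	Df(3L)BSC362	61C
psg2	2	25	66CD	Df(3L)Exel6105	64D
psg5	2	34	67EF	Df(3L)Exel6112	66B
psg15	1	28.1	67B	Df(3L)BSC388	66B
psg23	1	23.5	66C	Df(3L)BSC673	67BD
psg16	1	40.7	70C	Df(3L)ED4457	68A
psg19	1	48.3	85AB	Df(3L)ED217	71B
psg3	2	44.4	72D	Df(3L)BSC774	72D
psg27	1	43.8	72A	Df(3L)ED4606	72D
psg21	1	43.8	72A	Df(3L)BSC775	75E
psg22	1	52.6	88B	Df(3L)BSC775	75E
psg10	1	55	88F	Df(3L)ED229	76A
psg14	1	45.6	73F	Df(3L)ED229	76D
psg26	1	50.5	87A	Df(3L)ED5100	82D
psg4	3	48.7	85D	Df(3R)Tpl10	83E
psg9	1	44.2	72C	Df(3R)BSC466	85A
psg20	1	44.8	72F	Df(3R)BSC507	85D
psg6	2	50.3	86F	Df(3R)BSC486	87D
psg7	3	66	91F	Df(3R)Exel6178	90F
psg25	1	69.5	92F	Df(3R)ED5938	92A
psg29	1	63.8	91C	Df(3R)BSC677	93D
psg11	1	70.3	93B	Df(3R)BSC677	93F
psg24	1	80.1	95A	Df(3R)BSC619	94E
psg13	1	79.8	95A	Df(3R)ED6187	95F
psg18	1	86.8	96C	Df(3R)Exel6203	96E
psg17	1	right of Pr	99A	Df(3R)BSC501	99A
psg12	1	right of Pr	100D	Df(3R)BSC503	99F
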