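index	start_col	end_col
1	21	30
2	49	57
3	82	89
4	108	114
5	129	137
6	167	174
7	196	201
8	217	226
9	256	264
10	288	294
11	314	321
12	351	359
13	381	388
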