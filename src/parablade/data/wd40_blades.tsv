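blade	strand	start	end
1	A	301	310
2	A	311	320
3	A	321	330
4	A	331	340
5	A	341	350
6	A	351	360
7	A	361	370
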