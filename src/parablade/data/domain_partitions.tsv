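protein	domain	start	end
Scer_Tup1	N	1	89
Scer_Tup1	M	90	317
Scer_Tup1	C	318	713
Spombe_Tup11	N	1	87
Spombe_Tup11	M	88	286
Spombe_Tup11	C	287	614
Soct_Tup11	N	1	87
Soct_Tup11	M	88	271
Soct_Tup11	C	272	601
Sjap_Tup11	N	1	87
Sjap_Tup11	M	88	303
Sjap_Tup11	C	304	630
Spombe_Tup12	N	1	104
Spombe_Tup12	M	105	259
Spombe_Tup12	C	260	586
Soct_Tup12	N	1	88
Soct_Tup12	M	89	228
Soct_Tup12	C	229	555
Sjap_Tup12	N	1	88
Sjap_Tup12	M	89	249
Sjap_Tup12	C	250	576
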