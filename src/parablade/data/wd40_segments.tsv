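protein	start	end
Scer_Tup1	282	713
Spombe_Tup11	282	614
Spombe_Tup12	271	586
Soct_Tup11	271	601
Soct_Tup12	240	555
Sjap_Tup11	293	630
Sjap_Tup12	253	576
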