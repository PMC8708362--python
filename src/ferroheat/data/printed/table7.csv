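x,H_lo_kA_per_m,H_hi_kA_per_m,f_hi_kHz,f_lo_kHz,provenance
0,10,30,500,167,table7_row1
0.05,10,40,500,125,table7_row2
0.1,10,50,500,100,table7_row3
0.2,20,50,250,100,table7_row4
0.4,30,50,167,100,table7_row5
1,30,50,167,100,table7_row5
0.67,40,50,125,100,table7_row6
0.8,40,50,125,100,table7_row6
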