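f_kHz,x,PsM_W_per_g,D_M_nm,provenance
100,0,31.69,17.4,table3_row1
100,0.05,21.14,11.5,table3_row2
100,0.1,11.85,9,table3_row3
100,0.2,6.45,7.2,table3_row4
100,0.4,3.96,6.2,table3_row5
100,0.67,3.05,5.9,table3_row6
100,0.8,3.03,5.9,table3_row7
100,1,4.11,6.7,table3_row8
250,0,77.6,16.7,table4_row1
250,0.05,48.95,11.1,table4_row2
250,0.1,26.59,8.6,table4_row3
250,0.2,14.23,6.9,table4_row4
250,0.4,8.66,,table4_row5_DM_truncated_in_print
250,0.67,6.81,5.6,table4_row6
250,0.8,6.62,5.6,table4_row7
250,1,9.13,6.4,table4_row8
500,0,152.1,16.1,table5_row1
500,0.05,91.06,10.7,table5_row2
500,0.1,48.13,8.3,table5_row3
500,0.2,25.61,6.7,table5_row4
500,0.4,15.48,5.8,table5_row5
500,0.67,12.2,5.4,table5_row6
500,0.8,11.88,5.4,table5_row7
500,1,16.25,6.2,table5_row8
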