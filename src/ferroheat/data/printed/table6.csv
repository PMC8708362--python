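H_kA_per_m,f_l_kHz,x,PsMl_W_per_g,D_Mo_nm,provenance
10,500,0,62.29,16.1,table6_H10
10,500,0.05,26.13,10.7,table6_H10
10,500,0.1,12.47,8.3,table6_H10
10,500,0.2,6.47,6.7,table6_H10
10,500,0.4,3.89,5.8,table6_H10
10,500,0.67,3.06,5.4,table6_H10
10,500,0.8,2.98,5.4,table6_H10
10,500,1,4.08,6.2,table6_H10
20,250,0,77.60,16.7,table6_H20
20,250,0.05,48.94,11.1,table6_H20
20,250,0.1,26.59,8.6,table6_H20
20,250,0.2,14.23,6.9,table6_H20
20,250,0.4,8.66,6.0,table6_H20
20,250,0.67,6.81,5.6,table6_H20
20,250,0.8,6.63,5.6,table6_H20
20,250,1,9.12,6.4,table6_H20
30,167,0,82.57,17.0,table6_H30
30,167,0.05,62.52,11.3,table6_H30
30,167,0.1,39.12,8.7,table6_H30
30,167,0.2,20.07,7.1,table6_H30
30,167,0.4,13.75,6.1,table6_H30
30,167,0.67,10.77,5.7,table6_H30
30,167,0.8,10.44,5.7,table6_H30
30,167,1,14.41,6.5,table6_H30
40,125,0,84.60,17.2,table6_H40
40,125,0.05,68.96,11.5,table6_H40
40,125,0.1,48.92,8.8,table6_H40
40,125,0.2,29.43,7.2,table6_H40
40,125,0.4,18.63,6.2,table6_H40
40,125,0.67,14.82,5.8,table6_H40
40,125,0.8,14.48,5.8,table6_H40
40,125,1,19.58,6.6,table6_H40
50,100,0,85.94,17.4,table6_H50
50,100,0.05,74.31,11.5,table6_H50
50,100,0.1,56.68,8.9,table6_H50
50,100,0.2,36.59,7.2,table6_H50
50,100,0.4,23.78,6.2,table6_H50
50,100,0.67,18.52,5.9,table6_H50
50,100,0.8,18.42,5.9,table6_H50
50,100,1,24.31,6.7,table6_H50
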