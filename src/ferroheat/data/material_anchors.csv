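x,K_J_per_m3,Ms_A_per_m,rho_kg_per_m3
0,11e3,480e3,5.24e3
0.05,38e3,477e3,5.243e3
0.1,82e3,474e3,5.245e3
0.2,156e3,469e3,5.25e3
0.4,245e3,458e3,5.26e3
0.67,294e3,443e3,5.27e3
0.8,290e3,436e3,5.28e3
1,200e3,425e3,5.29e3
1.1,180e3,,
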