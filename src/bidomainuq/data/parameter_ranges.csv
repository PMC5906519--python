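name,min,mean,max
ROT,60,100,140
g_b,3.25,6.5,9.75
g_il,1.2,2.4,3.6
g_el,1.2,2.4,3.6
g_it,0.12,0.24,0.36
g_et,0.8,1.6,2.4
g_in,0.05,0.1,0.15
g_en,0.5,1.0,1.5
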