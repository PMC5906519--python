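study,type,animal,g_il,g_el,g_it,g_et,g_in,g_en
Bauer,PE,Rabbit,0.65,,0.042,,0.033,
Clerc,E,Calf,1.7,6.3,0.19,2.4,,
Hand,T,,1.0,3.0,0.03,1.6,,
Hooks,PE,Pig,2.6,2.6,0.26,2.5,0.08,1.1
Johnston2011,T,,1.9,3.2,0.35,2.2,0.08,1.2
Johnston2013,T,,2.4,2.4,0.35,2.0,0.08,1.1
Johnston2011b,T,,3.1,2.0,0.35,2.2,0.08,1.2
Krassowska,T,,0.7,3.0,0.003,1.5,,
LeGuyader1995,E,Dog,0.6,1.3,0.39,1.3,,
LeGuyader2001,E,Dog,2.0,3.9,0.19,1.7,,
MacLachlan,T,,3.0,2.0,1.0,1.7,0.32,1.4
Roberts1982,E,Dog,3.4,1.2,0.6,0.8,,
Roberts1979,E,Dog,2.8,2.2,0.26,1.3,,
Roth1997,T,,3.5,3.0,0.3,1.8,,
Roth1988,T,,1.9,1.9,0.2,0.9,,
Stinstra,T,,1.6,2.1,0.05,0.6,,
Trayanova,T,,2.0,3.0,0.14,0.32,,
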