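wavelength_nm,R,G,B
400,0.000000,0.000005,0.044991
410,0.000000,0.000025,0.110434
420,0.000000,0.000117,0.230238
430,0.000001,0.000494,0.407704
440,0.000003,0.001834,0.613209
450,0.000015,0.006013,0.783369
460,0.000063,0.017400,0.850000
470,0.000237,0.044432,0.783369
480,0.000816,0.100129,0.613209
490,0.002541,0.199131,0.407704
500,0.007167,0.349485,0.230238
510,0.018316,0.541294,0.110434
520,0.042405,0.739861,0.044991
530,0.088944,0.892442,0.015568
540,0.169013,0.950000,0.004576
550,0.290960,0.892442,0.001142
560,0.453789,0.739861,0.000242
570,0.641180,0.541294,0.000044
580,0.820755,0.349485,0.000007
590,0.951817,0.199131,0.000001
600,1.000000,0.100129,0.000000
610,0.951817,0.044432,0.000000
620,0.820755,0.017400,0.000000
630,0.641180,0.006013,0.000000
640,0.453789,0.001834,0.000000
650,0.290960,0.000494,0.000000
660,0.169013,0.000117,0.000000
670,0.088944,0.000025,0.000000
680,0.042405,0.000005,0.000000
690,0.018316,0.000001,0.000000
700,0.007167,0.000000,0.000000
710,0.002541,0.000000,0.000000
720,0.000816,0.000000,0.000000
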