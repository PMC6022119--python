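wavelength_nm,R,G,B
400,0.000000,0.000003,0.046913
410,0.000000,0.000020,0.124568
420,0.000000,0.000105,0.272083
430,0.000002,0.000483,0.488844
440,0.000009,0.001930,0.722464
450,0.000032,0.006715,0.878293
460,0.000111,0.020335,0.878293
470,0.000354,0.053616,0.722464
480,0.001043,0.123086,0.488844
490,0.002836,0.246017,0.272083
500,0.007116,0.428126,0.124568
510,0.016484,0.648674,0.046913
520,0.035248,0.855716,0.014533
530,0.069574,0.982836,0.003703
540,0.126773,0.982836,0.000776
550,0.213235,0.855716,0.000134
560,0.331091,0.648674,0.000019
570,0.474563,0.428126,0.000002
580,0.627909,0.246017,0.000000
590,0.766929,0.123086,0.000000
600,0.864710,0.053616,0.000000
610,0.900000,0.020335,0.000000
620,0.864710,0.006715,0.000000
630,0.766929,0.001930,0.000000
640,0.627909,0.000483,0.000000
650,0.474563,0.000105,0.000000
660,0.331091,0.000020,0.000000
670,0.213235,0.000003,0.000000
680,0.126773,0.000000,0.000000
690,0.069574,0.000000,0.000000
700,0.035248,0.000000,0.000000
710,0.016484,0.000000,0.000000
720,0.007116,0.000000,0.000000
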