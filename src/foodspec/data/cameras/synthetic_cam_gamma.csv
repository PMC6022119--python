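wavelength_nm,R,G,B
400,0.000000,0.000013,0.042893
410,0.000000,0.000056,0.098468
420,0.000000,0.000214,0.196814
430,0.000000,0.000734,0.342501
440,0.000001,0.002287,0.518939
450,0.000005,0.006450,0.684572
460,0.000026,0.016484,0.786269
470,0.000123,0.038164,0.786269
480,0.000520,0.080049,0.684572
490,0.001930,0.152112,0.518939
500,0.006330,0.261864,0.342501
510,0.018316,0.408410,0.196814
520,0.046771,0.577062,0.098468
530,0.105399,0.738679,0.042893
540,0.209611,0.856635,0.016268
550,0.367879,0.900000,0.005372
560,0.569783,0.856635,0.001544
570,0.778801,0.738679,0.000387
580,0.939413,0.577062,0.000084
590,1.000000,0.408410,0.000016
600,0.939413,0.261864,0.000003
610,0.778801,0.152112,0.000000
620,0.569783,0.080049,0.000000
630,0.367879,0.038164,0.000000
640,0.209611,0.016484,0.000000
650,0.105399,0.006450,0.000000
660,0.046771,0.002287,0.000000
670,0.018316,0.000734,0.000000
680,0.006330,0.000214,0.000000
690,0.001930,0.000056,0.000000
700,0.000520,0.000013,0.000000
710,0.000123,0.000003,0.000000
720,0.000026,0.000001,0.000000
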