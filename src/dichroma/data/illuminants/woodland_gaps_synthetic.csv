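# Synthetic stand-in irradiance table: woodland gaps (yellow/red-shifted gap light)
# Constructed to carry the qualitative spectral shape its name implies;
# NOT a measured habitat irradiance. Replace with measured data for
# quantitative work. Relative photon irradiance, arbitrary scale.
wl,irradiance
300,17.9688
305,18.3312
310,18.7456
315,19.2176
320,19.7530
325,20.3576
330,21.0374
335,21.7983
340,22.6461
345,23.5861
350,24.6236
355,25.7629
360,27.0080
365,28.3618
370,29.8263
375,31.4025
380,33.0899
385,34.8870
390,36.7907
395,38.7964
400,40.8983
405,43.0888
410,45.3592
415,47.6992
420,50.0977
425,52.5423
430,55.0198
435,57.5167
440,60.0187
445,62.5119
450,64.9822
455,67.4162
460,69.8010
465,72.1247
470,74.3765
475,76.5470
480,78.6282
485,80.6133
490,82.4974
495,84.2771
500,85.9502
505,87.5161
510,88.9753
515,90.3296
520,91.5813
525,92.7335
530,93.7898
535,94.7540
540,95.6296
545,96.4203
550,97.1290
555,97.7583
560,98.3101
565,98.7854
570,99.1846
575,99.5072
580,99.7521
585,99.9172
590,100.0000
595,99.9975
600,99.9063
605,99.7227
610,99.4430
615,99.0637
620,98.5815
625,97.9932
630,97.2967
635,96.4899
640,95.5719
645,94.5424
650,93.4020
655,92.1523
660,90.7957
665,89.3356
670,87.7762
675,86.1227
680,84.3808
685,82.5571
690,80.6590
695,78.6941
700,76.6706
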