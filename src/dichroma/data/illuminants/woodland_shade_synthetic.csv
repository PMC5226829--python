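# Synthetic stand-in irradiance table: woodland shade (bluish-grey shade light)
# Constructed to carry the qualitative spectral shape its name implies;
# NOT a measured habitat irradiance. Replace with measured data for
# quantitative work. Relative photon irradiance, arbitrary scale.
wl,irradiance
300,27.5008
305,28.8409
310,30.3049
315,31.8968
320,33.6197
325,35.4752
330,37.4637
335,39.5843
340,41.8342
345,44.2088
350,46.7019
355,49.3052
360,52.0084
365,54.7994
370,57.6640
375,60.5862
380,63.5485
385,66.5314
390,69.5145
395,72.4761
400,75.3936
405,78.2441
410,81.0043
415,83.6514
420,86.1628
425,88.5171
430,90.6940
435,92.6751
440,94.4436
445,95.9852
450,97.2880
455,98.3428
460,99.1434
465,99.6862
470,99.9709
475,100.0000
480,99.7789
485,99.3158
490,98.6212
495,97.7083
500,96.5921
505,95.2893
510,93.8180
515,92.1975
520,90.4476
525,88.5886
530,86.6407
535,84.6237
540,82.5570
545,80.4587
550,78.3462
555,76.2353
560,74.1402
565,72.0739
570,70.0472
575,68.0697
580,66.1488
585,64.2905
590,62.4991
595,60.7776
600,59.1273
605,57.5484
610,56.0401
615,54.6005
620,53.2268
625,51.9160
630,50.6641
635,49.4672
640,48.3210
645,47.2211
650,46.1632
655,45.1431
660,44.1569
665,43.2008
670,42.2715
675,41.3660
680,40.4816
685,39.6159
690,38.7673
695,37.9341
700,37.1151
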