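# Synthetic stand-in irradiance table: blue sky (Rayleigh-scattered skylight)
# Constructed to carry the qualitative spectral shape its name implies;
# NOT a measured habitat irradiance. Replace with measured data for
# quantitative work. Relative photon irradiance, arbitrary scale.
wl,irradiance
300,100.0000
305,93.6647
310,87.8280
315,82.4436
320,77.4701
325,72.8704
330,68.6114
335,64.6630
340,60.9987
345,57.5941
350,54.4276
355,51.4794
360,48.7317
365,46.1683
370,43.7747
375,41.5374
380,39.4445
385,37.4848
390,35.6484
395,33.9259
400,32.3092
405,30.7904
410,29.3625
415,28.0191
420,26.7542
425,25.5625
430,24.4388
435,23.3786
440,22.3776
445,21.4319
450,20.5379
455,19.6922
460,18.8917
465,18.1336
470,17.4151
475,16.7339
480,16.0876
485,15.4740
490,14.8914
495,14.3377
500,13.8112
505,13.3105
510,12.8339
515,12.3802
520,11.9479
525,11.5359
530,11.1431
535,10.7684
540,10.4108
545,10.0694
550,9.7433
555,9.4317
560,9.1338
565,8.8489
570,8.5763
575,8.3154
580,8.0657
585,7.8265
590,7.5972
595,7.3775
600,7.1669
605,6.9648
610,6.7709
615,6.5848
620,6.4061
625,6.2345
630,6.0696
635,5.9111
640,5.7588
645,5.6122
650,5.4713
655,5.3356
660,5.2051
665,5.0794
670,4.9583
675,4.8417
680,4.7293
685,4.6210
690,4.5165
695,4.4158
700,4.3186
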