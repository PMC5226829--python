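# Synthetic stand-in irradiance table: forest shade (green-dominated canopy light)
# Constructed to carry the qualitative spectral shape its name implies;
# NOT a measured habitat irradiance. Replace with measured data for
# quantitative work. Relative photon irradiance, arbitrary scale.
wl,irradiance
300,7.4093
305,7.4103
310,7.4118
315,7.4141
320,7.4173
325,7.4221
330,7.4288
335,7.4384
340,7.4518
345,7.4705
350,7.4964
355,7.5318
360,7.5799
365,7.6445
370,7.7307
375,7.8446
380,7.9937
385,8.1871
390,8.4359
395,8.7528
400,9.1529
405,9.6534
410,10.2735
415,11.0347
420,11.9603
425,13.0751
430,14.4048
435,15.9752
440,17.8118
445,19.9381
450,22.3748
455,25.1380
460,28.2386
465,31.6799
470,35.4570
475,39.5550
480,43.9485
485,48.6006
490,53.4628
495,58.4750
500,63.5667
505,68.6577
510,73.6604
515,78.4819
520,83.0268
525,87.2001
530,90.9107
535,94.0748
540,96.6184
545,98.4809
550,99.6174
555,100.0000
560,99.6197
565,98.4865
570,96.6293
575,94.0949
580,90.9465
585,87.2616
590,83.1296
595,78.6492
600,73.9249
605,69.0645
610,64.1752
615,59.3605
620,54.7158
625,50.3253
630,46.2573
635,42.5610
640,39.2635
645,36.3682
650,33.8546
655,31.6810
660,29.7889
665,28.1093
670,26.5706
675,25.1066
680,23.6639
685,22.2065
690,20.7191
695,19.2059
700,17.6876
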