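# Synthetic stand-in irradiance table: cloudy sky (near-flat overcast light)
# Constructed to carry the qualitative spectral shape its name implies;
# NOT a measured habitat irradiance. Replace with measured data for
# quantitative work. Relative photon irradiance, arbitrary scale.
wl,irradiance
300,91.4463
305,91.8857
310,92.3240
315,92.7604
320,93.1936
325,93.6228
330,94.0467
335,94.4643
340,94.8745
345,95.2762
350,95.6682
355,96.0495
360,96.4189
365,96.7754
370,97.1180
375,97.4456
380,97.7572
385,98.0518
390,98.3286
395,98.5867
400,98.8252
405,99.0434
410,99.2406
415,99.4162
420,99.5695
425,99.7002
430,99.8076
435,99.8916
440,99.9517
445,99.9879
450,100.0000
455,99.9879
460,99.9517
465,99.8916
470,99.8076
475,99.7002
480,99.5695
485,99.4162
490,99.2406
495,99.0434
500,98.8252
505,98.5867
510,98.3286
515,98.0518
520,97.7572
525,97.4456
530,97.1180
535,96.7754
540,96.4189
545,96.0495
550,95.6682
555,95.2762
560,94.8745
565,94.4643
570,94.0467
575,93.6228
580,93.1936
585,92.7604
590,92.3240
595,91.8857
600,91.4463
605,91.0070
610,90.5686
615,90.1321
620,89.6983
625,89.2682
630,88.8424
635,88.4219
640,88.0072
645,87.5991
650,87.1981
655,86.8048
660,86.4198
665,86.0435
670,85.6763
675,85.3185
680,84.9706
685,84.6327
690,84.3052
695,83.9881
700,83.6816
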