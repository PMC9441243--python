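wavelength_nm,relative_power
300,0.0341
310,3.2945
320,20.236
330,37.0535
340,39.9488
350,44.9117
360,46.6383
370,52.0891
380,49.9755
390,54.6482
400,82.7549
410,91.486
420,93.4318
430,86.6823
440,104.865
450,117.008
460,117.812
470,114.861
480,115.923
490,108.811
500,109.354
510,107.802
520,104.79
530,107.689
540,104.405
550,104.046
560,100.0
570,96.3342
580,95.788
590,88.6856
600,90.0062
610,89.5991
620,87.6987
630,83.2886
640,83.6992
650,80.0268
660,80.2146
670,82.2778
680,78.2842
690,69.7213
700,71.6091
710,74.349
720,61.604
730,69.8856
740,75.087
750,63.5927
760,46.4182
770,66.8054
780,63.3828
790,63.8434
800,59.4519
810,50.623
820,57.4406
830,60.3125
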