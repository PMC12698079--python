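wavelength_nm,value
380.0,105.2518
385.0,106.3602
390.0,107.3639
395.0,108.2654
400.0,109.0673
405.0,109.7725
410.0,110.3838
415.0,110.9044
420.0,111.3373
425.0,111.6857
430.0,111.9527
435.0,112.1416
440.0,112.2555
445.0,112.2977
450.0,112.2712
455.0,112.1793
460.0,112.0251
465.0,111.8115
470.0,111.5416
475.0,111.2182
480.0,110.8442
485.0,110.4225
490.0,109.9556
495.0,109.4462
500.0,108.8968
505.0,108.31
510.0,107.688
515.0,107.0332
520.0,106.3478
525.0,105.6338
530.0,104.8934
535.0,104.1286
540.0,103.3411
545.0,102.5328
550.0,101.7054
555.0,100.8606
560.0,100.0
565.0,99.125
570.0,98.2372
575.0,97.3377
580.0,96.4281
585.0,95.5094
590.0,94.583
595.0,93.6498
600.0,92.711
605.0,91.7675
610.0,90.8204
615.0,89.8704
620.0,88.9185
625.0,87.9655
630.0,87.012
635.0,86.0589
640.0,85.1067
645.0,84.1562
650.0,83.2079
655.0,82.2623
660.0,81.32
665.0,80.3815
670.0,79.4472
675.0,78.5175
680.0,77.5928
685.0,76.6736
690.0,75.7601
695.0,74.8526
700.0,73.9514
705.0,73.0569
710.0,72.1692
715.0,71.2886
720.0,70.4153
725.0,69.5494
730.0,68.6912
735.0,67.8408
740.0,66.9983
745.0,66.1638
750.0,65.3375
755.0,64.5195
760.0,63.7099
765.0,62.9086
770.0,62.1158
775.0,61.3316
780.0,60.5559
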