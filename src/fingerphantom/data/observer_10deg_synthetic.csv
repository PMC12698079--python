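wavelength_nm,xbar,ybar,zbar
380.0,0.008924,0.000284,0.024818
385.0,0.015809,0.000433,0.048257
390.0,0.026714,0.000655,0.089616
395.0,0.043055,0.00098,0.15813
400.0,0.066191,0.001452,0.264088
405.0,0.097062,0.002131,0.41627
410.0,0.135762,0.003101,0.618131
415.0,0.181126,0.004472,0.863767
420.0,0.230496,0.006397,1.135416
425.0,0.279788,0.009073,1.404349
430.0,0.32395,0.012764,1.635962
435.0,0.357783,0.017807,1.798047
440.0,0.376937,0.024629,1.8694
445.0,0.378834,0.033754,1.845384
450.0,0.363257,0.045813,1.738166
455.0,0.332403,0.061532,1.571765
460.0,0.290411,0.081717,1.374286
465.0,0.242495,0.107209,1.170597
470.0,0.193945,0.138826,0.977939
475.0,0.149277,0.17728,0.805162
480.0,0.111706,0.223075,0.654645
485.0,0.083016,0.276405,0.525201
490.0,0.063765,0.337048,0.414542
495.0,0.053681,0.404293,0.320649
500.0,0.052107,0.4769,0.242106
505.0,0.058374,0.553119,0.177849
510.0,0.072036,0.63077,0.12679
515.0,0.092968,0.707375,0.08757
520.0,0.121341,0.780343,0.05853
525.0,0.15752,0.847173,0.037833
530.0,0.201918,0.905648,0.02364
535.0,0.254835,0.954005,0.014277
540.0,0.316301,0.991034,0.008332
545.0,0.385939,1.016124,0.004699
550.0,0.462863,1.02923,0.002561
555.0,0.545604,1.030789,0.001349
560.0,0.632102,1.021601,0.000686
565.0,0.719745,1.002694,0.000337
570.0,0.805474,0.975208,0.00016
575.0,0.885943,0.940298,7.4e-05
580.0,0.957726,0.899081,3.3e-05
585.0,1.017554,0.85261,1.4e-05
590.0,1.062563,0.801879,6e-06
595.0,1.090519,0.747837,2e-06
600.0,1.1,0.691418,1e-06
605.0,1.090519,0.633545,0.0
610.0,1.062563,0.575142,0.0
615.0,1.017554,0.51712,0.0
620.0,0.957726,0.460351,0.0
625.0,0.885943,0.405647,0.0
630.0,0.805474,0.353722,0.0
635.0,0.719745,0.305172,0.0
640.0,0.632101,0.260448,0.0
645.0,0.545601,0.219856,0.0
650.0,0.462855,0.183548,0.0
655.0,0.385919,0.15154,0.0
660.0,0.316248,0.12372,0.0
665.0,0.254707,0.09988,0.0
670.0,0.201621,0.079731,0.0
675.0,0.15686,0.062932,0.0
680.0,0.119941,0.049115,0.0
685.0,0.090137,0.037901,0.0
690.0,0.066577,0.028918,0.0
695.0,0.048331,0.021816,0.0
700.0,0.034483,0.016274,0.0
705.0,0.02418,0.012002,0.0
710.0,0.016665,0.008753,0.0
715.0,0.011288,0.006311,0.0
720.0,0.007515,0.004499,0.0
725.0,0.004917,0.003171,0.0
730.0,0.003162,0.00221,0.0
735.0,0.001999,0.001523,0.0
740.0,0.001242,0.001038,0.0
745.0,0.000758,0.000699,0.0
750.0,0.000455,0.000466,0.0
755.0,0.000268,0.000307,0.0
760.0,0.000155,0.0002,0.0
765.0,8.9e-05,0.000129,0.0
770.0,5e-05,8.2e-05,0.0
775.0,2.7e-05,5.2e-05,0.0
780.0,1.5e-05,3.2e-05,0.0
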