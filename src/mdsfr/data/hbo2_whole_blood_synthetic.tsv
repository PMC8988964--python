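# fully oxygenated synthetic whole-blood absorption table (NOT digitised literature data)
# smooth Gaussian-band stand-in at whole-blood magnitudes, 150 g/L total hemoglobin
# columns: wavelength_nm	mu_a_mm^-1
400.0	206.214395
402.0	218.488141
404.0	229.588726
406.0	239.269147
408.0	247.306789
410.0	253.511914
412.0	257.735104
414.0	259.873240
416.0	259.873682
418.0	257.736431
420.0	253.514125
422.0	247.309885
424.0	239.273128
426.0	229.593592
428.0	218.493893
430.0	206.221032
432.0	193.037303
434.0	179.211063
436.0	165.007809
438.0	150.681978
440.0	136.469800
442.0	122.583452
444.0	109.206687
446.0	96.492001
448.0	84.559303
450.0	73.495999
452.0	63.358320
454.0	54.173671
456.0	45.943771
458.0	38.648322
460.0	32.248971
462.0	26.693334
464.0	21.918901
466.0	17.856651
468.0	14.434282
470.0	11.578964
472.0	9.219603
474.0	7.288582
476.0	5.723038
478.0	4.465693
480.0	3.465310
482.0	2.676842
484.0	2.061339
486.0	1.585694
488.0	1.222283
490.0	0.948584
492.0	0.746825
494.0	0.603718
496.0	0.510328
498.0	0.462111
500.0	0.459128
502.0	0.506411
504.0	0.614412
506.0	0.799411
508.0	1.083684
510.0	1.495212
512.0	2.066637
514.0	2.833239
516.0	3.829754
518.0	5.086036
520.0	6.621769
522.0	8.440742
524.0	10.525424
526.0	12.832792
528.0	15.292419
530.0	17.807677
532.0	20.260576
534.0	22.520251
536.0	24.454503
538.0	25.943222
540.0	26.892148
542.0	27.245279
544.0	26.994369
546.0	26.184382
548.0	24.914221
550.0	23.332476
552.0	21.628154
554.0	20.016401
556.0	18.719260
558.0	17.941803
560.0	17.844851
562.0	18.516996
564.0	19.950432
566.0	22.026548
568.0	24.517269
570.0	27.106185
572.0	29.429346
574.0	31.130236
576.0	31.918552
578.0	31.619843
580.0	30.204222
582.0	27.787249
584.0	24.603217
586.0	20.958179
588.0	17.174745
590.0	13.541532
592.0	10.277294
594.0	7.514526
596.0	5.301727
598.0	3.619318
600.0	2.402333
602.0	1.563425
604.0	1.011681
606.0	0.665170
608.0	0.457274
610.0	0.338124
612.0	0.272957
614.0	0.239042
616.0	0.222371
618.0	0.214779
620.0	0.211753
622.0	0.210923
624.0	0.211105
626.0	0.211736
628.0	0.212559
630.0	0.213464
632.0	0.214404
634.0	0.215362
636.0	0.216331
638.0	0.217307
640.0	0.218291
642.0	0.219283
644.0	0.220281
646.0	0.221287
648.0	0.222299
650.0	0.223319
652.0	0.224347
654.0	0.225382
656.0	0.226424
658.0	0.227473
660.0	0.228530
662.0	0.229595
664.0	0.230668
666.0	0.231748
668.0	0.232835
670.0	0.233931
672.0	0.235034
674.0	0.236146
676.0	0.237265
678.0	0.238392
680.0	0.239528
682.0	0.240671
684.0	0.241823
686.0	0.242983
688.0	0.244152
690.0	0.245328
692.0	0.246513
694.0	0.247707
696.0	0.248909
698.0	0.250120
700.0	0.251340
702.0	0.252568
704.0	0.253805
706.0	0.255051
708.0	0.256306
710.0	0.257569
712.0	0.258842
714.0	0.260124
716.0	0.261416
718.0	0.262716
720.0	0.264026
722.0	0.265345
724.0	0.266674
726.0	0.268012
728.0	0.269360
730.0	0.270717
732.0	0.272084
734.0	0.273461
736.0	0.274848
738.0	0.276245
740.0	0.277651
742.0	0.279068
744.0	0.280495
746.0	0.281932
748.0	0.283380
750.0	0.284838
752.0	0.286306
754.0	0.287785
756.0	0.289275
758.0	0.290775
760.0	0.292286
762.0	0.293807
764.0	0.295340
766.0	0.296884
768.0	0.298439
770.0	0.300004
772.0	0.301581
774.0	0.303170
776.0	0.304770
778.0	0.306381
780.0	0.308004
782.0	0.309638
784.0	0.311284
786.0	0.312942
788.0	0.314612
790.0	0.316294
792.0	0.317988
794.0	0.319694
796.0	0.321412
798.0	0.323142
800.0	0.324885
802.0	0.326641
804.0	0.328409
806.0	0.330190
808.0	0.331983
810.0	0.333789
812.0	0.335609
814.0	0.337441
816.0	0.339286
818.0	0.341145
820.0	0.343017
822.0	0.344902
824.0	0.346801
826.0	0.348714
828.0	0.350640
830.0	0.352580
832.0	0.354534
834.0	0.356502
836.0	0.358484
838.0	0.360481
840.0	0.362491
842.0	0.364516
844.0	0.366556
846.0	0.368610
848.0	0.370679
850.0	0.372763
852.0	0.374861
854.0	0.376975
856.0	0.379104
858.0	0.381248
860.0	0.383407
862.0	0.385582
864.0	0.387773
866.0	0.389979
868.0	0.392201
870.0	0.394439
872.0	0.396693
874.0	0.398963
876.0	0.401250
878.0	0.403553
880.0	0.405872
882.0	0.408208
884.0	0.410561
886.0	0.412930
888.0	0.415317
890.0	0.417721
892.0	0.420142
894.0	0.422580
896.0	0.425036
898.0	0.427509
900.0	0.430000
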