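# fully deoxygenated synthetic whole-blood absorption table (NOT digitised literature data)
# smooth Gaussian-band stand-in at whole-blood magnitudes, 150 g/L total hemoglobin
# columns: wavelength_nm	mu_a_mm^-1
400.0	138.700009
402.0	153.250685
404.0	168.180265
406.0	183.309198
408.0	198.436671
410.0	213.344483
412.0	227.801881
414.0	241.571221
416.0	254.414295
418.0	266.099071
420.0	276.406607
422.0	285.137841
424.0	292.119970
426.0	297.212135
428.0	300.310140
430.0	301.350000
432.0	300.310140
434.0	297.212135
436.0	292.119971
438.0	285.137842
440.0	276.406609
442.0	266.099074
444.0	254.414301
446.0	241.571231
448.0	227.801898
450.0	213.344513
452.0	198.436721
454.0	183.309282
456.0	168.180404
458.0	153.250911
460.0	138.700374
462.0	124.684272
464.0	111.332216
466.0	98.747193
468.0	87.005771
470.0	76.159131
472.0	66.234829
474.0	57.239094
476.0	49.159539
478.0	41.968113
480.0	35.624159
482.0	30.077440
484.0	25.271039
486.0	21.144034
488.0	17.633897
490.0	14.678576
492.0	12.218223
494.0	10.196590
496.0	8.562084
498.0	7.268501
500.0	6.275469
502.0	5.548626
504.0	5.059559
506.0	4.785525
508.0	4.708989
510.0	4.817002
512.0	5.100425
514.0	5.553047
516.0	6.170600
518.0	6.949714
520.0	7.886838
522.0	8.977178
524.0	10.213687
526.0	11.586156
528.0	13.080481
530.0	14.678124
532.0	16.355848
534.0	18.085738
536.0	19.835545
538.0	21.569358
540.0	23.248581
542.0	24.833177
544.0	26.283132
546.0	27.560042
548.0	28.628744
550.0	29.458882
552.0	30.026313
554.0	30.314252
556.0	30.314083
558.0	30.025778
560.0	29.457891
562.0	28.627135
564.0	27.557556
566.0	26.279382
568.0	24.827598
570.0	23.240361
572.0	21.557346
574.0	19.818121
576.0	18.060646
578.0	16.319966
580.0	14.627168
582.0	13.008621
584.0	11.485518
586.0	10.073721
588.0	8.783865
590.0	7.621690
592.0	6.588556
594.0	5.682072
596.0	4.896800
598.0	4.224980
600.0	3.657226
602.0	3.163349
604.0	2.752740
606.0	2.414654
608.0	2.138767
610.0	1.915442
612.0	1.735911
614.0	1.592373
616.0	1.478033
618.0	1.387078
620.0	1.314626
622.0	1.256645
624.0	1.209856
626.0	1.171634
628.0	1.139909
630.0	1.113071
632.0	1.089883
634.0	1.069411
636.0	1.050956
638.0	1.034002
640.0	1.018173
642.0	1.003200
644.0	0.988890
646.0	0.975107
648.0	0.961757
650.0	0.948776
652.0	0.936121
654.0	0.923763
656.0	0.911684
658.0	0.899875
660.0	0.888331
662.0	0.877051
664.0	0.866040
666.0	0.855305
668.0	0.844856
670.0	0.834705
672.0	0.824871
674.0	0.815372
676.0	0.806232
678.0	0.797479
680.0	0.789144
682.0	0.781262
684.0	0.773875
686.0	0.767024
688.0	0.760758
690.0	0.755128
692.0	0.750188
694.0	0.745996
696.0	0.742608
698.0	0.740084
700.0	0.738480
702.0	0.737853
704.0	0.738254
706.0	0.739728
708.0	0.742311
710.0	0.746032
712.0	0.750906
714.0	0.756934
716.0	0.764102
718.0	0.772375
720.0	0.781704
722.0	0.792014
724.0	0.803211
726.0	0.815181
728.0	0.827786
730.0	0.840868
732.0	0.854252
734.0	0.867745
736.0	0.881138
738.0	0.894215
740.0	0.906750
742.0	0.918516
744.0	0.929287
746.0	0.938843
748.0	0.946978
750.0	0.953499
752.0	0.958236
754.0	0.961043
756.0	0.961801
758.0	0.960423
760.0	0.956857
762.0	0.951083
764.0	0.943116
766.0	0.933008
768.0	0.920842
770.0	0.906733
772.0	0.890825
774.0	0.873285
776.0	0.854301
778.0	0.834078
780.0	0.812832
782.0	0.790786
784.0	0.768164
786.0	0.745188
788.0	0.722072
790.0	0.699021
792.0	0.676225
794.0	0.653856
796.0	0.632069
798.0	0.610998
800.0	0.590754
802.0	0.571429
804.0	0.553092
806.0	0.535792
808.0	0.519558
810.0	0.504401
812.0	0.490318
814.0	0.477289
816.0	0.465283
818.0	0.454259
820.0	0.444170
822.0	0.434959
824.0	0.426569
826.0	0.418938
828.0	0.412003
830.0	0.405704
832.0	0.399979
834.0	0.394771
836.0	0.390025
838.0	0.385689
840.0	0.381716
842.0	0.378061
844.0	0.374686
846.0	0.371556
848.0	0.368637
850.0	0.365903
852.0	0.363329
854.0	0.360893
856.0	0.358578
858.0	0.356368
860.0	0.354250
862.0	0.352212
864.0	0.350244
866.0	0.348339
868.0	0.346491
870.0	0.344693
872.0	0.342941
874.0	0.341231
876.0	0.339561
878.0	0.337927
880.0	0.336327
882.0	0.334760
884.0	0.333225
886.0	0.331719
888.0	0.330242
890.0	0.328793
892.0	0.327371
894.0	0.325975
896.0	0.324605
898.0	0.323259
900.0	0.321939
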