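# Synthetic band-calibration profile (VNIR 407-995 nm, 186 bands).
# Piecewise-linear stand-in anchored at published (band, wavelength) pairs;
# not a vendor calibration table. One center wavelength (nm) per line.
407.00
410.33
413.67
417.00
420.33
423.66
427.00
430.33
433.66
436.99
440.33
443.66
446.99
450.32
453.66
456.99
460.32
463.66
466.99
470.32
473.65
476.99
480.32
483.65
486.98
490.32
493.65
496.98
500.31
503.65
506.98
510.31
513.64
516.98
520.31
523.64
526.98
530.31
533.64
536.97
540.31
543.64
546.97
550.30
553.64
556.97
560.30
563.63
566.97
570.30
573.63
576.97
580.30
583.63
586.96
590.30
593.63
596.96
600.29
603.63
606.96
610.29
613.62
616.96
620.29
623.92
627.55
631.17
634.80
638.43
642.06
645.69
649.31
652.94
656.57
660.20
663.83
667.45
671.08
674.71
678.34
681.97
685.60
689.22
692.85
696.48
700.11
703.74
707.36
710.99
714.62
718.25
721.88
725.50
729.13
732.76
736.39
740.02
743.64
747.27
750.90
754.53
758.16
761.78
765.41
769.04
772.67
776.30
779.93
783.55
787.18
790.81
794.44
798.07
801.69
805.32
808.95
812.58
816.21
819.83
823.46
827.09
829.71
832.34
834.96
837.58
840.21
842.83
845.46
848.08
850.70
853.33
855.95
858.57
861.20
863.82
866.44
869.07
871.69
874.31
876.94
879.56
882.19
884.81
887.43
890.06
892.68
895.30
897.93
900.55
903.17
905.80
908.42
911.05
913.67
916.29
918.92
921.54
924.16
926.79
929.41
932.03
934.66
937.28
939.90
942.53
945.15
947.78
950.40
953.02
955.65
958.27
960.89
963.52
966.14
968.76
971.39
974.01
976.63
979.26
981.88
984.51
987.13
989.75
992.38
995.00
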