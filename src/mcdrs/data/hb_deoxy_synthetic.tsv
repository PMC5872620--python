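# species: Hb
# reference_concentration_g_dl: 15.0
# units: wavelength_nm	mua_per_mm
# provenance: synthetic re-tabulation -- monotone (PCHIP) interpolation
#   through widely published visible/NIR extinction anchor values with
#   isosbestic points pinned at 506/522/548/569/586/798 nm; not a copy of
#   any single published compilation. Replaceable via this text format.
450	45.516217
451	44.162648
452	42.833568
453	41.529956
454	40.252792
455	39.003055
456	37.781725
457	36.589782
458	35.428204
459	34.297971
460	33.200064
461	32.123630
462	31.060172
463	30.014206
464	28.990244
465	27.992800
466	27.026388
467	26.095522
468	25.204716
469	24.358482
470	23.561336
471	22.797462
472	22.050539
473	21.324317
474	20.622548
475	19.948984
476	19.307374
477	18.701472
478	18.135027
479	17.611792
480	17.135517
481	16.696175
482	16.280414
483	15.886998
484	15.514689
485	15.162252
486	14.828450
487	14.512046
488	14.211805
489	13.926490
490	13.654865
491	13.387429
492	13.118768
493	12.853780
494	12.597359
495	12.354402
496	12.129804
497	11.928462
498	11.755271
499	11.615127
500	11.512925
501	11.432461
502	11.357097
503	11.291082
504	11.238667
505	11.204101
506	11.191635
507	11.219023
508	11.294621
509	11.408580
510	11.551050
511	11.712182
512	11.882126
513	12.051034
514	12.209056
515	12.359814
516	12.514905
517	12.676445
518	12.846547
519	13.027325
520	13.220895
521	13.429370
522	13.654865
523	13.906690
524	14.190107
525	14.501156
526	14.835878
527	15.190311
528	15.560498
529	15.942477
530	16.332290
531	16.742342
532	17.183819
533	17.650926
534	18.137870
535	18.638857
536	19.148093
537	19.659785
538	20.168138
539	20.667359
540	21.151654
541	21.625066
542	22.095898
543	22.564745
544	23.032202
545	23.498866
546	23.965331
547	24.432194
548	24.900048
549	25.370840
550	25.843126
551	26.312423
552	26.774245
553	27.271750
554	27.762352
555	28.112958
556	28.342901
557	28.522446
558	28.594894
559	28.555531
560	28.449765
561	28.296080
562	28.112958
563	27.829246
564	27.391890
565	26.846519
566	26.238760
567	25.438155
568	24.458395
569	23.561336
570	22.815938
571	22.112495
572	21.444868
573	20.806916
574	20.192500
575	19.595479
576	19.009714
577	18.434445
578	17.879352
579	17.353956
580	16.867775
581	16.417877
582	15.992421
583	15.587561
584	15.199450
585	14.824243
586	14.458092
587	14.116993
588	13.799839
589	13.477133
590	13.119380
591	12.706137
592	12.244826
593	11.747748
594	11.227204
595	10.695495
596	10.164923
597	9.647788
598	9.156391
599	8.703033
600	8.300016
601	7.931572
602	7.574421
603	7.229597
604	6.898133
605	6.581062
606	6.279416
607	5.994229
608	5.726534
609	5.477364
610	5.247752
611	5.033091
612	4.828077
613	4.632703
614	4.446959
615	4.270835
616	4.104323
617	3.947412
618	3.800094
619	3.662360
620	3.534200
621	3.413061
622	3.296599
623	3.185124
624	3.078944
625	2.978367
626	2.883702
627	2.795257
628	2.713341
629	2.638261
630	2.570328
631	2.507882
632	2.448971
633	2.393457
634	2.341201
635	2.292067
636	2.245915
637	2.202610
638	2.162013
639	2.123986
640	2.088391
641	2.054388
642	2.021379
643	1.989594
644	1.959263
645	1.930614
646	1.903878
647	1.879284
648	1.857062
649	1.837440
650	1.820649
651	1.806354
652	1.793827
653	1.782703
654	1.772619
655	1.763209
656	1.754111
657	1.744961
658	1.735393
659	1.725045
660	1.713552
661	1.701201
662	1.688531
663	1.675553
664	1.662279
665	1.648720
666	1.634888
667	1.620794
668	1.606450
669	1.591868
670	1.577058
671	1.562034
672	1.546806
673	1.531385
674	1.515784
675	1.500014
676	1.484087
677	1.468014
678	1.451806
679	1.435476
680	1.419035
681	1.402129
682	1.384461
683	1.366125
684	1.347217
685	1.327831
686	1.308062
687	1.288004
688	1.267754
689	1.247405
690	1.227052
691	1.206791
692	1.186715
693	1.166921
694	1.147503
695	1.128555
696	1.110173
697	1.092451
698	1.075484
699	1.059367
700	1.044196
701	1.029505
702	1.014799
703	1.000129
704	0.985541
705	0.971086
706	0.956811
707	0.942766
708	0.928999
709	0.915558
710	0.902494
711	0.889854
712	0.877686
713	0.866041
714	0.854966
715	0.844511
716	0.834723
717	0.825652
718	0.817347
719	0.809856
720	0.803227
721	0.797025
722	0.790820
723	0.784678
724	0.778661
725	0.772833
726	0.767258
727	0.762000
728	0.757122
729	0.752688
730	0.748761
731	0.745406
732	0.742685
733	0.740663
734	0.739403
735	0.738969
736	0.739184
737	0.739814
738	0.740838
739	0.742237
740	0.743990
741	0.746076
742	0.748474
743	0.751165
744	0.754127
745	0.757341
746	0.760784
747	0.764438
748	0.768281
749	0.772293
750	0.776453
751	0.782876
752	0.793002
753	0.805801
754	0.820239
755	0.835286
756	0.849910
757	0.863080
758	0.873765
759	0.880932
760	0.883550
761	0.882739
762	0.880429
763	0.876803
764	0.872045
765	0.866338
766	0.859866
767	0.852813
768	0.845362
769	0.837697
770	0.830002
771	0.821262
772	0.810571
773	0.798274
774	0.784715
775	0.770238
776	0.755187
777	0.739906
778	0.724741
779	0.710034
780	0.696130
781	0.682831
782	0.669667
783	0.656581
784	0.643514
785	0.630409
786	0.617206
787	0.603848
788	0.590276
789	0.576433
790	0.562259
791	0.546343
792	0.528129
793	0.508839
794	0.489698
795	0.471929
796	0.456757
797	0.445405
798	0.439098
799	0.435943
800	0.433200
801	0.430821
802	0.428756
803	0.426956
804	0.425373
805	0.423957
806	0.422660
807	0.421432
808	0.420226
809	0.418991
810	0.417678
811	0.416309
812	0.414941
813	0.413577
814	0.412225
815	0.410888
816	0.409572
817	0.408282
818	0.407024
819	0.405802
820	0.404622
821	0.403488
822	0.402407
823	0.401383
824	0.400422
825	0.399529
826	0.398708
827	0.397966
828	0.397306
829	0.396736
830	0.396259
831	0.395844
832	0.395454
833	0.395088
834	0.394744
835	0.394421
836	0.394116
837	0.393829
838	0.393557
839	0.393299
840	0.393053
841	0.392818
842	0.392592
843	0.392373
844	0.392159
845	0.391950
846	0.391742
847	0.391536
848	0.391328
849	0.391118
850	0.390904
851	0.390684
852	0.390458
853	0.390227
854	0.389992
855	0.389754
856	0.389513
857	0.389272
858	0.389031
859	0.388790
860	0.388551
861	0.388314
862	0.388081
863	0.387853
864	0.387629
865	0.387412
866	0.387203
867	0.387001
868	0.386809
869	0.386626
870	0.386455
871	0.386295
872	0.386149
873	0.386016
874	0.385898
875	0.385795
876	0.385709
877	0.385640
878	0.385590
879	0.385560
880	0.385549
881	0.385549
882	0.385549
883	0.385549
884	0.385549
885	0.385549
886	0.385549
887	0.385549
888	0.385549
889	0.385549
890	0.385549
891	0.385549
892	0.385549
893	0.385549
894	0.385549
895	0.385549
896	0.385549
897	0.385549
898	0.385549
899	0.385549
900	0.385549
901	0.385531
902	0.385477
903	0.385388
904	0.385266
905	0.385112
906	0.384927
907	0.384712
908	0.384470
909	0.384201
910	0.383906
911	0.383586
912	0.383244
913	0.382880
914	0.382495
915	0.382091
916	0.381669
917	0.381230
918	0.380776
919	0.380308
920	0.379828
921	0.379335
922	0.378832
923	0.378321
924	0.377801
925	0.377275
926	0.376744
927	0.376209
928	0.375672
929	0.375133
930	0.374594
931	0.374057
932	0.373521
933	0.372990
934	0.372464
935	0.371944
936	0.371432
937	0.370928
938	0.370435
939	0.369954
940	0.369485
941	0.369014
942	0.368528
943	0.368027
944	0.367514
945	0.366987
946	0.366451
947	0.365904
948	0.365349
949	0.364786
950	0.364218
951	0.363644
952	0.363067
953	0.362488
954	0.361907
955	0.361326
956	0.360746
957	0.360168
958	0.359594
959	0.359025
960	0.358462
961	0.357906
962	0.357358
963	0.356820
964	0.356292
965	0.355777
966	0.355274
967	0.354786
968	0.354314
969	0.353858
970	0.353420
971	0.352993
972	0.352571
973	0.352151
974	0.351736
975	0.351325
976	0.350918
977	0.350516
978	0.350117
979	0.349724
980	0.349334
981	0.348950
982	0.348571
983	0.348196
984	0.347827
985	0.347463
986	0.347104
987	0.346751
988	0.346403
989	0.346061
990	0.345725
991	0.345395
992	0.345071
993	0.344753
994	0.344441
995	0.344136
996	0.343837
997	0.343545
998	0.343260
999	0.342982
1000	0.342710
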