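# species: HbO2
# reference_concentration_g_dl: 15.0
# units: wavelength_nm	mua_per_mm
# provenance: synthetic re-tabulation -- monotone (PCHIP) interpolation
#   through widely published visible/NIR extinction anchor values with
#   isosbestic points pinned at 506/522/548/569/586/798 nm; not a copy of
#   any single published compilation. Replaceable via this text format.
450	33.637020
451	32.431063
452	31.259898
453	30.127011
454	29.035886
455	27.990009
456	26.992865
457	26.047941
458	25.158721
459	24.328691
460	23.561336
461	22.843546
462	22.159261
463	21.507537
464	20.887434
465	20.298009
466	19.738320
467	19.207427
468	18.704387
469	18.228258
470	17.778099
471	17.346526
472	16.927963
473	16.524179
474	16.136939
475	15.768014
476	15.419169
477	15.092174
478	14.788796
479	14.510803
480	14.259963
481	14.031097
482	13.816972
483	13.616272
484	13.427682
485	13.249887
486	13.081571
487	12.921419
488	12.768117
489	12.620348
490	12.476798
491	12.331519
492	12.182021
493	12.032175
494	11.885853
495	11.746926
496	11.619267
497	11.506746
498	11.413236
499	11.342607
500	11.298732
501	11.270515
502	11.245003
503	11.223277
504	11.206419
505	11.195511
506	11.191635
507	11.207891
508	11.253586
509	11.324110
510	11.414850
511	11.521197
512	11.638539
513	11.762265
514	11.887765
515	12.026445
516	12.191742
517	12.382091
518	12.595929
519	12.831690
520	13.087809
521	13.362723
522	13.654865
523	13.976364
524	14.340263
525	14.746369
526	15.194489
527	15.684431
528	16.216001
529	16.789008
530	17.403259
531	18.124518
532	18.989823
533	19.955891
534	20.979440
535	22.017188
536	23.025851
537	24.162348
538	25.493228
539	26.839660
540	28.022809
541	28.863842
542	29.183927
543	28.966622
544	28.393352
545	27.582089
546	26.650803
547	25.717466
548	24.900048
549	24.135895
550	23.312422
551	22.472706
552	21.659823
553	20.916851
554	20.286865
555	19.812941
556	19.429534
557	19.067011
558	18.762320
559	18.552410
560	18.474229
561	18.527729
562	18.677569
563	18.907755
564	19.202296
565	19.545199
566	20.181878
567	21.215933
568	22.418656
569	23.561336
570	24.654550
571	25.797140
572	26.892798
573	27.845215
574	28.777730
575	29.620435
576	29.987155
577	29.768881
578	29.181973
579	28.328300
580	27.309730
581	25.503379
582	22.861446
583	20.348426
584	18.287157
585	16.334967
586	14.458092
587	12.538440
588	10.609383
589	8.864356
590	7.496789
591	6.444459
592	5.516383
593	4.712860
594	4.034184
595	3.480652
596	3.009023
597	2.584116
598	2.218312
599	1.923996
600	1.713552
601	1.565509
602	1.445261
603	1.345487
604	1.258863
605	1.178067
606	1.101050
607	1.030552
608	0.966433
609	0.908554
610	0.856776
611	0.808750
612	0.762389
613	0.717947
614	0.675679
615	0.635839
616	0.598679
617	0.564456
618	0.533421
619	0.505830
620	0.481936
621	0.460833
622	0.441350
623	0.423343
624	0.406670
625	0.391188
626	0.376755
627	0.363226
628	0.350461
629	0.338315
630	0.326646
631	0.315287
632	0.304220
633	0.293523
634	0.283274
635	0.273553
636	0.264438
637	0.256008
638	0.248341
639	0.241517
640	0.235613
641	0.230424
642	0.225657
643	0.221266
644	0.217203
645	0.213420
646	0.209871
647	0.206508
648	0.203283
649	0.200149
650	0.197058
651	0.194004
652	0.191018
653	0.188115
654	0.185310
655	0.182618
656	0.180053
657	0.177629
658	0.175362
659	0.173266
660	0.171355
661	0.169539
662	0.167728
663	0.165935
664	0.164175
665	0.162461
666	0.160809
667	0.159231
668	0.157743
669	0.156357
670	0.155090
671	0.153954
672	0.152963
673	0.152132
674	0.151475
675	0.151007
676	0.150644
677	0.150295
678	0.149962
679	0.149647
680	0.149352
681	0.149077
682	0.148824
683	0.148595
684	0.148392
685	0.148216
686	0.148068
687	0.147950
688	0.147864
689	0.147812
690	0.147794
691	0.147911
692	0.148245
693	0.148766
694	0.149446
695	0.150257
696	0.151172
697	0.152160
698	0.153195
699	0.154248
700	0.155291
701	0.156416
702	0.157723
703	0.159192
704	0.160802
705	0.162533
706	0.164365
707	0.166278
708	0.168251
709	0.170265
710	0.172299
711	0.174333
712	0.176347
713	0.178320
714	0.180233
715	0.182065
716	0.183817
717	0.185513
718	0.187166
719	0.188792
720	0.190403
721	0.192015
722	0.193640
723	0.195294
724	0.196990
725	0.198742
726	0.200564
727	0.202471
728	0.204477
729	0.206594
730	0.208839
731	0.211264
732	0.213902
733	0.216734
734	0.219743
735	0.222912
736	0.226221
737	0.229654
738	0.233193
739	0.236819
740	0.240515
741	0.244263
742	0.248044
743	0.251842
744	0.255639
745	0.259415
746	0.263155
747	0.266839
748	0.270450
749	0.273970
750	0.277381
751	0.280726
752	0.284058
753	0.287379
754	0.290690
755	0.293991
756	0.297283
757	0.300567
758	0.303843
759	0.307114
760	0.310378
761	0.313638
762	0.316894
763	0.320147
764	0.323397
765	0.326646
766	0.329879
767	0.333087
768	0.336274
769	0.339445
770	0.342607
771	0.345764
772	0.348921
773	0.352085
774	0.355259
775	0.358450
776	0.361663
777	0.364903
778	0.368176
779	0.371486
780	0.374839
781	0.378282
782	0.381844
783	0.385506
784	0.389248
785	0.393050
786	0.396893
787	0.400758
788	0.404625
789	0.408474
790	0.412286
791	0.416041
792	0.419720
793	0.423303
794	0.426771
795	0.430104
796	0.433282
797	0.436287
798	0.439098
799	0.441669
800	0.444020
801	0.446227
802	0.448368
803	0.450519
804	0.452758
805	0.455162
806	0.457733
807	0.460410
808	0.463180
809	0.466026
810	0.468934
811	0.471887
812	0.474871
813	0.477871
814	0.480870
815	0.483853
816	0.486806
817	0.489712
818	0.492557
819	0.495325
820	0.498001
821	0.500612
822	0.503196
823	0.505755
824	0.508290
825	0.510800
826	0.513288
827	0.515753
828	0.518197
829	0.520621
830	0.523026
831	0.525412
832	0.527780
833	0.530132
834	0.532467
835	0.534788
836	0.537094
837	0.539387
838	0.541667
839	0.543936
840	0.546195
841	0.548452
842	0.550709
843	0.552958
844	0.555188
845	0.557389
846	0.559551
847	0.561665
848	0.563719
849	0.565706
850	0.567614
851	0.569459
852	0.571263
853	0.573029
854	0.574760
855	0.576458
856	0.578126
857	0.579766
858	0.581382
859	0.582975
860	0.584548
861	0.586103
862	0.587644
863	0.589172
864	0.590691
865	0.592203
866	0.593710
867	0.595215
868	0.596720
869	0.598229
870	0.599743
871	0.601282
872	0.602858
873	0.604468
874	0.606106
875	0.607767
876	0.609447
877	0.611140
878	0.612842
879	0.614548
880	0.616253
881	0.617952
882	0.619639
883	0.621311
884	0.622963
885	0.624588
886	0.626184
887	0.627744
888	0.629264
889	0.630738
890	0.632163
891	0.633533
892	0.634842
893	0.636088
894	0.637263
895	0.638364
896	0.639386
897	0.640324
898	0.641172
899	0.641926
900	0.642582
901	0.643186
902	0.643786
903	0.644380
904	0.644964
905	0.645537
906	0.646094
907	0.646632
908	0.647150
909	0.647643
910	0.648109
911	0.648545
912	0.648947
913	0.649313
914	0.649641
915	0.649926
916	0.650166
917	0.650357
918	0.650498
919	0.650585
920	0.650614
921	0.650614
922	0.650614
923	0.650614
924	0.650614
925	0.650614
926	0.650614
927	0.650614
928	0.650614
929	0.650614
930	0.650614
931	0.650614
932	0.650614
933	0.650614
934	0.650614
935	0.650614
936	0.650614
937	0.650614
938	0.650614
939	0.650614
940	0.650614
941	0.650584
942	0.650494
943	0.650350
944	0.650153
945	0.649907
946	0.649615
947	0.649281
948	0.648908
949	0.648500
950	0.648058
951	0.647588
952	0.647092
953	0.646573
954	0.646034
955	0.645480
956	0.644913
957	0.644336
958	0.643753
959	0.643167
960	0.642582
961	0.641967
962	0.641293
963	0.640561
964	0.639773
965	0.638931
966	0.638037
967	0.637093
968	0.636102
969	0.635064
970	0.633982
971	0.632857
972	0.631693
973	0.630490
974	0.629251
975	0.627978
976	0.626672
977	0.625335
978	0.623970
979	0.622579
980	0.621162
981	0.619690
982	0.618132
983	0.616489
984	0.614765
985	0.612963
986	0.611085
987	0.609133
988	0.607111
989	0.605022
990	0.602867
991	0.600649
992	0.598372
993	0.596038
994	0.593649
995	0.591209
996	0.588719
997	0.586183
998	0.583604
999	0.580983
1000	0.578324
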