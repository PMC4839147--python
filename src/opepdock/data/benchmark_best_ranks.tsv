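# Best-hit ranks per target on a published protein-protein docking test
# benchmark (Dockground 2.0 subset, 2000 retained decoys per target), under
# the original grid-based docking score (zdock) and the coarse-grained 8-6
# rescoring function before (e86) and after (e86_trained) contact-potential
# training.  "-" marks targets without any hit in the top 2000.
target	class	zdock	e86	e86_trained
1ARO	enzyme_inhibitor	-	-	-
1AVW	enzyme_inhibitor	2	12	46
1BTH	enzyme_inhibitor	366	218	106
1CHO	enzyme_inhibitor	3	5	1
1GPQ	enzyme_inhibitor	1271	438	109
1ID5	enzyme_inhibitor	72	11	4
1KU6	enzyme_inhibitor	10	19	14
1OFH	enzyme_inhibitor	-	-	-
1PPF	enzyme_inhibitor	12	12	1
1T6G	enzyme_inhibitor	2	22	5
1TX6	enzyme_inhibitor	539	28	87
1UGH	enzyme_inhibitor	1	1	1
1XX9	enzyme_inhibitor	279	17	8
2BKR	enzyme_inhibitor	4	18	33
2D26	enzyme_inhibitor	-	-	-
2FI4	enzyme_inhibitor	335	69	48
2KAI	enzyme_inhibitor	269	287	75
3SIC	enzyme_inhibitor	1	1	1
1A2Y	antigen_antibody	5	21	3
1G6V	antigen_antibody	1344	1485	705
1G9M	antigen_antibody	1	4	3
2BNQ	antigen_antibody	-	-	-
1BZQ	antigen_antibody	13	22	7
1FBI	antigen_antibody	609	1113	1174
1FNS	antigen_antibody	729	1055	1906
1H0D	antigen_antibody	159	17	1
1JTP	antigen_antibody	13	1	2
1MQ8	antigen_antibody	16	1479	565
1NBY	antigen_antibody	-	-	-
1NCB	antigen_antibody	-	-	-
1NSN	antigen_antibody	562	695	949
1PKQ	antigen_antibody	-	-	-
1SQ2	antigen_antibody	1	1	2
1Z3G	antigen_antibody	6	1273	378
1BUI	other	343	1332	573
1F6A	other	-	-	-
1FM9	other	1	2	2
1G20	other	11	15	12
1G4A	other	-	-	-
1G4U	other	-	-	-
1GHQ	other	-	-	-
1GLB	other	1021	1356	1352
1HXY	other	-	-	-
1JWM	other	-	-	-
1K90	other	-	-	-
1K93	other	-	-	-
1L9B	other	-	-	-
1MA9	other	1	1	1
1NBF	other	91	105	106
1NVU	other	1020	555	192
1OMW	other	-	-	-
1OOK	other	171	639	237
1P7Q	other	3	13	21
1R4M	other	9	201	27
1RQQ	other	-	-	-
1S6V	other	1	9	7
1SQ0	other	-	-	-
1U0N	other	-	-	-
1U7F	other	149	1508	969
1UEX	other	25	14	11
1V7P	other	76	52	13
1WLI	other	-	-	-
1YI5	other	-	-	-
1ZY8	other	202	143	54
2A42	other	-	-	-
2ATQ	other	-	-	-
2B4S	other	-	-	-
2CKH	other	1	1	1
2G45	other	912	682	438
2GD4	other	-	-	-
2GOO	other	-	-	-
2GY7	other	-	-	-
3FAP	other	143	80	95
3PRO	other	158	41	136
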