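#id=PV998923
#length=15788
#circular=true
Gene	Start	End	Strand	Length	StartCodon	StopCodon	Anticodon
cox1	1	1557	+	1557	ATG	TAA
trnR	1567	1635	+	69			UCG
nad4l	1636	1932	+	297	ATG	TAA
cox2	1933	2620	+	688	ATG	T
trnK	2621	2686	+	66			CUU
atp8	2687	2851	+	165	ATG	TAA
atp6	2845	3528	+	684	ATG	TAA
cox3	3531	4313	+	783	ATG	TAA
trnS2	4312	4382	-	71			UGA
nad3	4401	4745	+	345	ATG	TAA
nad4	4749	6105	+	1357	ATG	T
trnH	6107	6174	+	68			GUG
trnS1	6176	6243	+	68			GCU
nad5	6244	8079	+	1836	ATG	TAA
nad6	8097	8585	-	489	ATG	TAG
cob	8594	9736	+	1143	ATG	TAA
trnF	9738	9808	+	71			GAA
rrnS	9808	10639	+	832
trnE	10641	10709	+	69			UUC
trnT	10711	10780	+	70			UGU
trnP	11227	11295	+	69			UGG
trnQ	11292	11361	-	70			UUG
trnN	11364	11433	+	70			GUU
trnL1	11435	11506	+	72			UAG
trnA	11506	11572	-	67			UGC
trnW	11573	11640	+	68			UCA
trnC	11641	11702	+	62			GCA
trnV	11706	11775	-	70			UAC
trnM	11799	11867	+	69			CAU
trnD	11872	11941	-	70			GUC
trnY	11942	12009	+	68			GUA
trnG	12009	12077	+	69			UCC
trnL2	12077	12147	+	71			UAA
nad1	12148	13119	+	972	ATG	TAA
trnL	13133	13200	+	68			GAU
nad2	13201	14244	+	1044	ATG	TAA
rrnL	14245	15637	+	1393
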