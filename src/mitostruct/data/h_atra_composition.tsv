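Gene	T_pct	C_pct	A_pct	G_pct	AT_pct	AT_skew	GC_skew
cox1	24.8	27.0	30.8	17.4	24.8	0.109	-0.216
nad4l	27.9	31.6	29.6	10.8	27.9	0.029	-0.492
cox2	23.1	28.8	34.2	14.0	23.1	0.193	-0.347
atp8	20.6	29.1	41.2	9.1	20.6	0.333	-0.524
atp6	24.7	31.4	32.5	11.4	24.7	0.136	-0.468
cox3	23.5	29.8	30.8	16.0	23.5	0.134	-0.302
nad3	24.9	30.4	31.0	13.6	24.9	0.109	-0.382
nad4	23.7	27.9	35.2	13.3	23.7	0.196	-0.355
nad5	25.4	25.5	36.0	13.1	25.4	0.172	-0.322
nad6	49.9	10.4	15.3	24.3	49.9	-0.530	0.400
cob	27.4	26.0	32.0	14.6	27.4	0.078	-0.280
nad1	28.3	25.6	31.3	14.8	28.3	0.050	-0.267
nad2	30.4	23.9	33.0	12.8	30.4	0.041	-0.300
rrnS	20.0	23.2	37.5	19.4	57.5	0.305	-0.090
rrnL	20.9	22.4	38.5	18.2	59.4	0.296	-0.102
trnR1	27.5	24.6	34.8	13.0	62.3	0.116	-0.308
trnK	22.7	25.8	34.8	16.7	57.6	0.211	-0.214
trnS2	36.6	14.1	23.9	25.4	60.6	-0.209	0.286
trnH	25.0	20.6	33.8	20.6	58.8	0.150	0.000
trnS1	23.5	25.0	23.5	27.9	47.1	0.000	0.056
trnF	26.8	18.3	33.8	21.1	60.6	0.116	0.071
trnE	20.3	24.6	33.3	21.7	53.6	0.243	-0.063
trnT	30.0	17.1	37.1	15.7	67.1	0.106	-0.043
trnP	23.2	17.4	37.7	21.7	60.9	0.238	0.111
trnQ	35.7	14.3	28.6	21.4	64.3	-0.111	0.200
trnN	25.7	17.1	35.7	21.4	61.4	0.163	0.111
trnL1	33.3	16.7	29.2	20.8	62.5	-0.067	0.111
trnA	37.3	13.4	25.4	23.9	62.7	-0.190	0.280
trnW	29.4	14.7	39.7	16.2	69.1	0.149	0.048
trnC	24.2	24.2	30.6	21.0	54.8	0.118	-0.071
trnV	32.9	18.6	22.9	25.7	55.7	-0.179	0.161
trnM	26.1	24.6	33.3	15.9	59.4	0.122	-0.214
trnD	32.9	15.7	31.4	20.0	64.3	-0.022	0.120
trnY	25.0	22.1	29.4	23.5	54.4	0.081	0.032
trnG	24.6	23.2	36.2	15.9	60.9	0.190	-0.185
trnL2	25.4	25.4	26.8	22.5	52.1	0.027	-0.059
trnI	23.5	26.5	29.4	20.6	52.9	0.111	-0.125
mitogenome	25.0	25.9	34.1	14.9	59.2	0.154	-0.268
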