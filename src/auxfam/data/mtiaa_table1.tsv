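gene	locus_id	orf_length_nt	introns	chromosome	start	end	length_aa	mol_wt_kda	pi
MtIAA1	Medtr1g070830	615	2	1	17318116	17319328	204	22.91	6.42
MtIAA2	Medtr1g093240	711	4	1	26193287	26196287	236	25.72	8.46
MtIAA3	Medtr1g093350	537	1	1	26247246	26248612	178	19.98	8.00
MtIAA4	Medtr2g100780	810	4	2	32192283	32195676	269	29.96	8.73
MtIAA5	Medtr2g101500	981	4	2	32562344	32565049	326	35.36	7.96
MtIAA6	Medtr2g102490	597	4	2	33070172	33071309	198	22.5	8.62
MtIAA7	Medtr3g106850	642	3	3	37913558	37914702	213	24.73	8.94
MtIAA8	Medtr4g060470	1086	2	4	18656418	18658053	361	39.46	5.93
MtIAA9	Medtr4g115070	1614	4	4	39660114	39669519	537	62.45	6.93
MtIAA10	Medtr4g124300	555	3	4	43252133	43253003	184	20.88	6.83
MtIAA11	Medtr4g128070	522	1	4	44708010	44709260	173	19.22	7.91
MtIAA12	Medtr5g030710	1008	6	5	12694370	12699892	335	36.26	8.25
MtIAA13	Medtr5g067350	1044	5	5	27469789	27473618	335	36.26	8.25
MtIAA14	Medtr7g110790	429	2	7	35419184	35419916	142	15.99	5.18
MtIAA15	Medtr8g014520	816	4	8	3132788	3136332	271	30.12	8.19
MtIAA16	Medtr8g067530	1071	7	8	17235080	17239117	356	38.67	6.62
MtIAA17	Medtr8g103030	882	4	8	30131713	30134764	293	31.89	7.85
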