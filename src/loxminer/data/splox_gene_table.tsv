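gene	sequence_id	coordinates	genomic_bp	orf_bp	protein_aa	mw_kda	pi	subfamily
SpLOX1	Spipo2G0068200	5245164:5249140 (-)	3977	2607	868	97.22	5.58	9-LOX
SpLOX2	Spipo2G0068500	5257861:5263185 (-)	5325	2535	844	95.40	6.12	9-LOX
SpLOX3	Spipo4G0070100	5947369:5951085 (+)	3717	2421	806	90.60	6.24	13-LOX
SpLOX4	Spipo7G0050500	4554161:4559214 (+)	5054	2751	916	102.81	7.10	13-LOX
SpLOX5	Spipo15G0045200	4070955:4073755 (-)	2801	2379	792	88.63	6.04	13-LOX
SpLOX6	Spipo28G0005500	470166:475175 (-)	5010	2715	904	102.13	6.29	13-LOX
SpLOX7	Spipo28G0005600	487129:491614 (+)	4486	2715	904	103.52	7.16	13-LOX
SpLOX8	Spipo28G0005700	497951:504441 (+)	6491	1914	637	71.66	6.99	13-LOX
SpLOX9	Spipo0G0030100	2519505:2523103 (+)	3599	2763	920	103.52	7.16	13-LOX
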