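gene_id	domain	aa_start	aa_end	source
SpLOX1	PLAT	55	162	HMMER
SpLOX1	LOX	175	846	HMMER
SpLOX1	5HIS	519	556	manual
SpLOX2	PLAT	71	165	HMMER
SpLOX2	LOX	178	822	HMMER
SpLOX2	5HIS	522	559	manual
SpLOX3	PLAT	16	131	CDART
SpLOX3	LOX	135	784	HMMER
SpLOX3	5HIS	479	516	manual
SpLOX4	PLAT	115	216	HMMER
SpLOX4	LOX	229	899	HMMER
SpLOX4	5HIS	567	604	manual
SpLOX5	PLAT	28	99	HMMER
SpLOX5	LOX	112	775	HMMER
SpLOX5	5HIS	447	484	manual
SpLOX6	PLAT	123	207	HMMER
SpLOX6	LOX	220	887	HMMER
SpLOX6	5HIS	557	594	manual
SpLOX7	PLAT	121	207	HMMER
SpLOX7	LOX	222	887	HMMER
SpLOX7	5HIS	557	594	manual
SpLOX8	PLAT	23	120	HMMER
SpLOX8	LOX	129	620	HMMER
SpLOX8	5HIS	466	503	manual
SpLOX9	PLAT	138	223	HMMER
SpLOX9	LOX	236	903	HMMER
SpLOX9	5HIS	574	611	manual
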