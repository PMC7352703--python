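Gene_ID	log2FC	p_adj	chr	start	end	strand	ENSEMBL_ID
MSTRG.3558	1.42	2.44E-03	12	47554682	47562366	-	NA
MSTRG.9270	-0.95	1.41E-02	2	11923739	11924922	+	NA
MSTRG.15739	-1.38	4.80E-03	6	88799040	88800470	-	NA
MSTRG.19846	1.86	1.64E-06	AEMK02000682.1	1430615	1441540	+	ENSSSCG00000035563
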