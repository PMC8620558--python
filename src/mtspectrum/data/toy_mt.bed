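toy_mt	9	102	toyA	0	+	CDS
toy_mt	109	179	toyT	0	+	tRNA
toy_mt	189	279	toyB	0	-	CDS
toy_mt	289	389	toyR	0	+	rRNA
toy_mt	399	499	toyC	0	+	CDS
toy_mt	509	589	toyD	0	+	D-loop
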