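##gff-version 3
toy_mt	mtspectrum	CDS	10	102	.	+	.	Name=toyA
toy_mt	mtspectrum	tRNA	110	179	.	+	.	Name=toyT
toy_mt	mtspectrum	CDS	190	279	.	-	.	Name=toyB
toy_mt	mtspectrum	rRNA	290	389	.	+	.	Name=toyR
toy_mt	mtspectrum	CDS	400	499	.	+	.	Name=toyC
toy_mt	mtspectrum	D-loop	510	589	.	+	.	Name=toyD
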