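Gene	Strand	Start	End	Kind	StartCodon	StopCodon	Anticodon
COX1	+	1	1531	PCG	ATA	T
tRNA-Leu2	+	1532	1599	tRNA			UAA
COX2	+	1603	2274	PCG	ATA	TAA
tRNA-Lys	+	2277	2349	tRNA			CUU
tRNA-Asp	+	2350	2412	tRNA			GUC
ATP8	+	2413	2571	PCG	ATT	TAA
ATP6	+	2552	3205	PCG	ATT	TAA
COX3	+	3205	3990	PCG	ATG	TAA
tRNA-Gly	+	3990	4052	tRNA			UCC
NAD3	+	4053	4406	PCG	ATT	TAA
tRNA-Ala	+	4406	4469	tRNA			UGC
tRNA-Arg	+	4469	4534	tRNA			UCG
tRNA-Asn	+	4534	4600	tRNA			GUU
tRNA-Ser1	+	4600	4661	tRNA			GCU
tRNA-Glu	+	4664	4729	tRNA			UUC
RR	+	4730	4922	noncoding
tRNA-Phe	-	4923	4987	tRNA			GAA
NAD5	-	4988	6658	PCG	ATT	TAA
tRNA-His	-	6711	6774	tRNA			GUG
NAD4	-	6775	8083	PCG	ATG	T
NAD4L	-	8092	8382	PCG	ATA	TAA
tRNA-Thr	+	8384	8445	tRNA			UGU
tRNA-Pro	-	8448	8517	tRNA			UGG
NAD6	+	8519	9013	PCG	ATT	TAA
CYTB	+	9013	10128	PCG	ATG	TAG
tRNA-Ser2	+	10127	10191	tRNA			UGA
NAD1	-	10202	11137	PCG	ATT	TAA
tRNA-Leu1	-	11138	11202	tRNA			UAG
rrnL	-	11202	12457	rRNA
tRNA-Val	-	12458	12519	tRNA			UAC
rrnS	-	12532	13298	rRNA
CR	+	13299	14407	noncoding
tRNA-Ile	+	14408	14471	tRNA			GAU
tRNA-Gln	-	14469	14534	tRNA			UUG
tRNA-Met	+	14539	14604	tRNA			CAU
NAD2	+	14605	15582	PCG	ATA	TAA
tRNA-Trp	+	15581	15642	tRNA			UCA
tRNA-Cys	-	15635	15702	tRNA			GCA
tRNA-Tyr	-	15705	15771	tRNA			GUA
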