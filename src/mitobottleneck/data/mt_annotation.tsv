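name	region	start	end	strand
CR_proximal	loop	1	576	+
TRNF	tRNA	577	647	+
RNR1	rRNA	648	1601	+
TRNV	tRNA	1602	1670	+
RNR2	rRNA	1671	3229	+
TRNL1	tRNA	3230	3304	+
ND1	coding	3307	4262	+
TRNI	tRNA	4263	4331	+
TRNQ	tRNA	4329	4400	-
TRNM	tRNA	4402	4469	+
ND2	coding	4470	5511	+
TRNW	tRNA	5512	5579	+
TRNA	tRNA	5587	5655	-
TRNN	tRNA	5657	5729	-
TRNC	tRNA	5761	5826	-
TRNY	tRNA	5826	5891	-
CO1	coding	5904	7445	+
TRNS1	tRNA	7446	7514	-
TRND	tRNA	7518	7585	+
CO2	coding	7586	8269	+
TRNK	tRNA	8295	8364	+
ATP8	coding	8366	8572	+
ATP6	coding	8527	9207	+
CO3	coding	9207	9990	+
TRNG	tRNA	9991	10058	+
ND3	coding	10059	10404	+
TRNR	tRNA	10405	10469	+
ND4L	coding	10470	10766	+
ND4	coding	10760	12137	+
TRNH	tRNA	12138	12206	+
TRNS2	tRNA	12207	12265	+
TRNL2	tRNA	12266	12336	+
ND5	coding	12337	14148	+
ND6	coding	14149	14673	-
TRNE	tRNA	14674	14742	-
CYB	coding	14747	15887	+
TRNT	tRNA	15888	15953	+
TRNP	tRNA	15956	16023	-
CR_distal	loop	16024	16569	+
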