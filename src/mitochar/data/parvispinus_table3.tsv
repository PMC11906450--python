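# Thrips parvispinus complete mitochondrial genome, published annotation summary.
# The printed intergenic value after cytB is 101, but the coordinates give
# 15285 - 15126 - 1 = 158 to the genome end; no gap convention reproduces
# 101, so the printed value is carried in intergenic_printed only for the
# record and is excluded from per-row gap cross-checks.
#genome_length=15285
#circular=true
#taxon=Thrips parvispinus
gene	type	start	end	strand	anticodon	start_codon	stop_codon	length_override	length_printed	intergenic_printed
nad5	PCG	146	1840	-	.	att	taa	.	1695	-5
nad4	PCG	1836	3157	-	.	ata	t	.	1322	47
nad4L	PCG	3205	3486	-	.	atg	taa	.	282	25
trnC	tRNA	3512	3574	+	gca	.	.	.	63	18
nad6	PCG	3593	4090	+	.	att	taa	.	498	100
rrnL	rRNA	4191	5338	+	.	.	.	.	1148	20
cox1	PCG	5359	6930	+	.	att	taa	.	1572	71
nad3	PCG	7002	7343	+	.	att	taa	.	342	-35
cox2	PCG	7309	8001	+	.	ata	taa	.	693	23
trnG	tRNA	8025	8087	+	tcc	.	.	.	63	3
trnK	tRNA	8091	8154	+	ttt	.	.	.	64	2
cox3	PCG	8157	8945	+	.	ttg	taa	.	789	4
trnN	tRNA	8950	9016	+	gtt	.	.	.	67	-4
trnS1	tRNA	9013	9073	+	tct	.	.	.	61	0
trnL1	tRNA	9074	9138	+	tag	.	.	.	65	42
trnE	tRNA	9181	9246	+	ttc	.	.	.	66	347
trnP	tRNA	9594	9659	-	tgg	.	.	.	66	34
trnY	tRNA	9694	9757	-	gta	.	.	.	64	57
nad2	PCG	9815	10825	+	.	att	taa	.	1011	17
nad1	PCG	10843	11772	+	.	att	taa	.	930	-4
trnM	tRNA	11769	11833	+	cat	.	.	.	65	1
trnA	tRNA	11835	11896	+	tgc	.	.	.	62	-1
trnF	tRNA	11896	11960	+	gaa	.	.	.	65	-2
rrnS	rRNA	11959	12711	+	.	.	.	.	753	8
atp8	PCG	12720	12879	+	.	att	t	.	160	41
atp6	PCG	12921	13535	+	.	att	taa	.	615	5
trnQ	tRNA	13541	13609	+	ttg	.	.	.	69	59
trnS2	tRNA	13669	13733	+	tga	.	.	.	65	3
trnD	tRNA	13737	13801	+	gtc	.	.	.	65	1
trnR	tRNA	13803	13870	+	tcg	.	.	.	68	0
trnT	tRNA	13871	13935	+	tgt	.	.	.	65	10
trnI	tRNA	13946	14012	+	gat	.	.	.	67	-32
cytB	PCG	13981	15126	+	.	ata	taa	.	1146	101
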