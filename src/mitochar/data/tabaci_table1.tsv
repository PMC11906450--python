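# Thrips tabaci complete mitochondrial genome, published annotation summary.
# Columns beyond the gene-table schema carry the printed length and
# intergenic-space values for cross-checking recomputed statistics.
# The printed atp8 length (126 bp, also used in the composition table and
# the 13-PCG total) differs from its coordinate span (203 bp); the
# published coordinates are kept and the printed length is carried as
# length_override.
#genome_length=15277
#circular=true
#taxon=Thrips tabaci
gene	type	start	end	strand	anticodon	start_codon	stop_codon	length_override	length_printed	intergenic_printed
nad5	PCG	205	1899	-	.	att	tag	.	1695	-12
trnH	tRNA	1888	1948	-	gtg	.	.	.	61	10
nad4	PCG	1959	2966	-	.	att	t	.	1008	292
nad4L	PCG	3259	3531	-	.	atg	taa	.	273	26
trnC	tRNA	3558	3617	+	gca	.	.	.	60	31
nad6	PCG	3649	4122	+	.	att	taa	.	474	51
rrnL	rRNA	4174	5325	+	.	.	.	.	1152	22
COX1	PCG	5348	6889	+	.	ata	taa	.	1542	65
nad3	PCG	6955	7305	+	.	att	taa	.	351	-1
COX2	PCG	7305	7964	+	.	ata	taa	.	660	11
trnG	tRNA	7976	8037	+	tcc	.	.	.	62	3
trnK	tRNA	8041	8102	+	ttt	.	.	.	62	10
COX3	PCG	8113	8895	+	.	ata	taa	.	783	0
trnN	tRNA	8896	8959	+	gtt	.	.	.	64	-3
trnT	tRNA	8957	9019	+	tgt	.	.	.	63	-1
trnL1	tRNA	9019	9082	+	tag	.	.	.	64	2
trnE	tRNA	9085	9147	+	ttc	.	.	.	63	8
trnS1	tRNA	9156	9212	+	tct	.	.	.	57	6
trnQ	tRNA	9219	9286	+	ttg	.	.	.	68	37
trnS2	tRNA	9324	9387	+	tga	.	.	.	64	0
trnD	tRNA	9388	9451	+	gtc	.	.	.	64	451
trnR	tRNA	9903	9968	-	tcg	.	.	.	66	18
ATP6	PCG	9987	10607	-	.	ata	taa	.	621	50
ATP8	PCG	10658	10860	-	.	att	t	126	203	-54
rrnS	rRNA	10807	11413	-	.	.	.	.	607	116
trnF	tRNA	11530	11594	-	gaa	.	.	.	65	-1
trnA	tRNA	11594	11656	-	tgc	.	.	.	63	2
trnM	tRNA	11659	11721	-	cat	.	.	.	63	-4
nad1	PCG	11718	12641	-	.	ata	taa	.	924	6
nad2	PCG	12648	13628	-	.	att	taa	.	981	73
trnY	tRNA	13702	13765	+	gta	.	.	.	64	-3
CYTB	PCG	13763	14908	-	.	ata	tag	.	1146	-29
trnI	tRNA	14880	14943	-	gat	.	.	.	64	2
trnP	tRNA	14946	15008	+	tgg	.	.	.	63	268
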