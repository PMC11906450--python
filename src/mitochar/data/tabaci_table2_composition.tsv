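# Thrips tabaci per-gene nucleotide composition as published: percentage
# of each base, total length in bp, AT/GC content and skews.  Skews are
# recomputable from the printed percentages to 3 decimals.
gene	pct_T	pct_C	pct_A	pct_G	total_bp	gc_pct	at_pct	gc_skew	at_skew
nad5	53.2	10.9	25.2	10.7	1695	21.60	78.40	-0.009	-0.357
nad4	51.8	10.8	24.4	13	1008	23.80	76.20	0.092	-0.360
nad4l	56.4	8.8	22.7	12.1	273	20.90	79.10	0.158	-0.426
nad6	44.7	9.9	37.8	7.6	474	17.50	82.50	-0.131	-0.084
cox1	37.5	15.9	32.3	14.3	1542	30.20	69.80	-0.053	-0.074
nad3	38.7	12.9	38.7	9.7	351	22.60	77.40	-0.142	0.000
cox2	35.6	16.2	36.2	12	660	28.20	71.80	-0.149	0.008
cox3	39.4	16.4	32.4	11.8	783	28.20	71.80	-0.163	-0.097
atp6	37.7	14.8	36.2	11.3	621	26.10	73.90	-0.134	-0.020
atp8	41.3	14.3	32.5	11.9	126	26.20	73.80	-0.092	-0.119
nad1	37.3	15.4	35.5	11.8	924	27.20	72.80	-0.132	-0.025
nad2	39.1	12	41.8	7.1	981	19.10	80.90	-0.257	0.033
cob	40.6	14.7	32.7	12	1146	26.70	73.30	-0.101	-0.108
rrnS	45.8	12.2	31	11	607	23.20	76.80	-0.052	-0.193
rrnL	32.5	9.8	46.8	10.9	1152	20.70	79.30	0.053	0.180
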