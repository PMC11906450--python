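# Thrips parvispinus per-gene nucleotide composition as published.
gene	length	pct_T	pct_C	pct_A	pct_G	gc_pct	at_pct	gc_skew	at_skew
nad5	1695	54.65	8.40	26.35	10.60	19.00	81.00	0.116	-0.349
nad4	1322	55.45	7.60	25.25	11.70	19.30	80.70	0.212	-0.374
nad4l	282	59.20	6.75	24.80	9.25	16.00	84.00	0.156	-0.410
nad6	498	40.40	9.60	42.00	8.00	17.60	82.40	-0.091	0.019
cox1	1572	36.40	14.20	36.40	13.00	27.20	72.80	-0.044	0.000
nad3	342	38.60	11.70	40.90	8.80	20.50	79.50	-0.141	0.029
cox2	693	34.50	14.30	39.20	12.00	26.30	73.70	-0.087	0.064
cox3	789	36.75	15.50	36.45	11.30	26.80	73.20	-0.157	-0.004
nad2	1011	40.50	11.60	42.50	5.40	17.00	83.00	-0.365	0.024
nad1	930	40.75	12.85	35.40	11.00	23.85	76.15	-0.078	-0.070
atp8	160	38.10	11.30	42.50	8.10	19.40	80.60	-0.165	0.055
atp6	615	39.20	13.30	37.10	10.40	23.70	76.30	-0.122	-0.028
cob	1146	40.00	13.75	35.10	11.15	24.90	75.10	-0.104	-0.065
rrnL	1148	32.35	9.10	47.25	11.30	20.40	79.60	0.108	0.187
rrnS	753	33.30	10.40	46.10	10.20	20.60	79.40	-0.010	0.161
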