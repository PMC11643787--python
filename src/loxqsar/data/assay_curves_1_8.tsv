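id	conc_uM	inhibition_pct	ic50_reported_umol
1	60	27.62	72.5
1	70	45.25	72.5
1	80	63.30	72.5
1	90	81.12	72.5
2	30	12.99	48.2
2	40	33.61	48.2
2	50	53.12	48.2
2	60	74.14	48.2
3	20	40.679	30.4
3	30	49.593	30.4
3	40	58.907	30.4
3	50	66.821	30.4
4	60	29.47	70.8
4	70	47.37	70.8
4	80	68.27	70.8
4	90	88.18	70.8
5	50	21.78	69.6
5	60	37.64	69.6
5	70	51.49	69.6
5	80	63.36	69.6
6	10	16.21	24.9
6	20	35.89	24.9
6	30	65.08	24.9
6	40	83.27	24.9
7	40	25.91	45.7
7	45	46.84	45.7
7	50	68.77	45.7
7	55	89.70	45.7
8	40	13.88	47.4
8	45	36.79	47.4
8	50	63.70	47.4
8	55	86.60	47.4
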