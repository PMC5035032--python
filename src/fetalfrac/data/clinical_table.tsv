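sample	depth	sensitivity	specificity	standard_cff	estimated_cff	corrected_cff
p-1	54	43.4	80	7.7	11.3	7.9
p-2	55	82.6	86.3	23.7	22.4	21.6
p-3	58	67.6	81.9	12.9	14	12.3
p-4	60	66.7	96.6	14.6	16.3	15.3
P-5	65	32.9	67.2	9.9	11.8	9.6
P-6	73	46.1	88.3	9.6	12.3	10.7
P-7	78	64.9	86.9	13.3	13.9	12.9
P-8	79	39.7	87.8	8.80	11.3	9.6
P-9_1	114	69.7	93.8	19.6	19.6	-
P-9_2	137	58.4	77.1	18.8	17.7	-
P-10	136	84.2	91	14.2	14.6	-
P-11	142	91.2	92.6	17.6	17.5	-
P-12	145	59.3	96.2	16.5	16.5	-
P-13	152	89.4	98.1	17.1	17.1	-
P-14_1	165	48.1	94.7	11.1	11.8	-
P-14_2	205	40.5	79.3	10.4	10.1	-
P-15	203	88.7	95.5	15.7	15.6	-
p-16	290	42.9	97.3	23.1	23.2	-
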