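aa	gc	omz_50	omz_85	omz_110	omz_200	bats_20	bats_50	bats_100	hot_25	hot_75	hot_110	hot_500	soil
Ala	0.83	31.5	30.2	21.8	20.1	35.5	27.6	28.0	45.4	44.2	26.2	26.8	5.5
Gly	0.83	26.8	24.7	17.8	16.4	18.7	16.1	16.7	19.0	23.4	14.4	-10.2	0.0
Pro	0.83	11.0	11.7	3.3	7.4	13.1	6.6	8.7	10.1	2.4	4.0	6.8	5.1
Arg	0.72	-3.3	-3.2	-11.7	1.8	23.2	14.2	9.7	11.9	0.9	4.1	-6.7	1.3
Trp	0.67	34.0	49.5	27.0	21.2	12.2	9.2	11.9	18.2	25.7	17.1	-9.3	16.3
Cys	0.50	-0.5	-5.1	-6.9	2.1	-2.6	-6.6	-9.5	-10.3	-8.9	-11.8	17.5	3.9
Asp	0.50	3.3	5.6	0.9	8.0	3.0	-0.8	-0.2	-0.1	0.4	-2.0	-2.9	-3.6
Glu	0.50	-7.0	-11.1	-2.4	2.8	0.7	-1.2	-1.0	-6.6	-8.9	-5.6	-21.7	-9.0
His	0.50	-4.1	-5.4	-7.8	-0.6	4.1	-1.4	-3.4	9.7	0.9	-4.5	-28.3	2.9
Gln	0.50	-1.3	1.3	-2.9	2.5	9.3	6.4	6.8	9.3	3.8	4.2	-10.8	-2.7
Ser	0.50	-5.4	-2.8	-3.4	-2.9	-8.5	-7.4	-5.2	-7.6	-6.3	-2.0	6.4	4.1
Thr	0.50	14.9	17.8	11.3	7.5	7.9	10.0	10.7	14.2	14.6	9.8	-17.4	1.3
Val	0.50	17.7	18.8	12.2	11.5	16.0	15.0	13.2	18.1	20.2	11.4	7.5	-4.1
Leu	0.39	-9.7	-11.0	-10.4	-8.1	-6.6	-6.7	-5.3	-7.2	-6.9	-2.2	7.8	4.4
Met	0.33	14.2	20.0	7.6	6.6	13.0	14.5	6.1	17.5	20.3	5.3	-0.5	-1.6
Phe	0.17	-10.5	-9.1	-6.9	-10.2	-15.9	-11.3	-9.6	-8.4	-5.8	-1.6	-3.6	4.3
Lys	0.17	-22.3	-28.6	-9.5	-17.8	-13.7	-8.4	-6.6	-25.1	-23.4	-11.5	15.9	-26.3
Asn	0.17	-23.6	-20.5	-14.8	-18.0	-25.1	-20.2	-19.2	-24.9	-23.0	-17.4	13.6	0.9
Tyr	0.17	-8.4	-6.7	-5.3	-4.8	-15.2	-9.3	-11.0	-1.9	-5.6	-7.7	25.7	5.4
Ile	0.11	-19.3	-21.8	-11.8	-18.2	-22.5	-18.2	-18.5	-23.0	-20.6	-17.5	-3.7	0.4
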