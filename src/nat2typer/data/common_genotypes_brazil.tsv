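genotype	n_subjects	brazil_percent	south_percent	southeast_percent	midwest_percent	northeast_percent	north_percent
NAT2*4/*4	55	5.7	6.4	3.9	8.5	6.4	6.3
NAT2*4/*13A	41	4.3	9.6	4.2	0	0	1.6
NAT2*12A/*12A	23	2.4	8.8	0	0.9	0	0
NAT2*13A/*13A	16	1.6	3.2	2.4	0	0	0
NAT2*12A/*12B	12	1.2	4.8	0	0	0	0
NAT2*4/*12A	11	1.1	0.41	1.8	1.9	0	1.0
NAT2*5B/*5B	109	11.4	10.5	12.2	11.3	9.0	12.1
NAT2*5B/*6A	87	9.1	2.4	11.6	11.3	18.0	8.4
NAT2*6A/*6A	54	5.6	7.2	2.9	8.5	7.6	5.8
NAT2*5B/*7B	25	2.6	0.8	3.0	0.9	5.1	4.2
NAT2*6A/*7B	17	1.8	0	1.2	3.8	3.8	3.2
NAT2*5A/*6A	12	1.2	0.8	0.6	0.94	2.5	2.6
NAT2*5B/*5C	12	1.2	0	2.4	0.9	1.3	1.0
NAT2*4/*5B	96	10.0	2.4	13.1	16.0	12.8	10.0
NAT2*4/*6A	68	7.1	1.2	7.2	14.1	7.7	10.6
NAT2*5B/*12A	37	3.9	11.3	1.8	0.9	0	1.0
NAT2*5B/*13A	30	3.1	0.4	6.8	0.9	3.8	1.0
NAT2*5B/*12B	24	2.5	8.8	0.3	0	0	0.5
NAT2*4/*5A	13	1.4	0	0.6	0	1.3	5.3
NAT2*4/*7B	13	1.4	0.4	0.9	1.9	1.3	3.2
NAT2*5C/*12A	12	1.2	4.3	0.3	0	0	0
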