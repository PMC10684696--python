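stratum	n_chromosomes	allele	percent
North	378	NAT2*4	25.1
North	378	NAT2*5A	6.6
North	378	NAT2*5B	27.2
North	378	NAT2*5C	1.6
North	378	NAT2*6A	19.6
North	378	NAT2*7B	7.4
North	378	NAT2*12A	1.3
North	378	NAT2*12B	0.3
North	378	NAT2*13A	2.4
North	378	NAT2*14B	2.4
Northeast	156	NAT2*4	19.8
Northeast	156	NAT2*5A	1.9
Northeast	156	NAT2*5B	32
Northeast	156	NAT2*5C	3.2
Northeast	156	NAT2*6A	26.9
Northeast	156	NAT2*7B	5.1
Northeast	156	NAT2*12A	1.9
Northeast	156	NAT2*12B	0
Northeast	156	NAT2*13A	2.6
Northeast	156	NAT2*14B	1.3
Midwest	212	NAT2*4	26.8
Midwest	212	NAT2*5A	0.5
Midwest	212	NAT2*5B	29.2
Midwest	212	NAT2*5C	1.4
Midwest	212	NAT2*6A	26.4
Midwest	212	NAT2*7B	4.2
Midwest	212	NAT2*12A	3.3
Midwest	212	NAT2*12B	0
Midwest	212	NAT2*13A	0.9
Midwest	212	NAT2*14B	0.9
Southeast	670	NAT2*4	20
Southeast	670	NAT2*5A	1
Southeast	670	NAT2*5B	33.8
Southeast	670	NAT2*5C	2.1
Southeast	670	NAT2*6A	16
Southeast	670	NAT2*7B	3.9
Southeast	670	NAT2*12A	3.4
Southeast	670	NAT2*12B	0.1
Southeast	670	NAT2*13A	11.2
Southeast	670	NAT2*14B	2.4
South	496	NAT2*4	14.7
South	496	NAT2*5A	1
South	496	NAT2*5B	23.8
South	496	NAT2*5C	5
South	496	NAT2*6A	9.9
South	496	NAT2*7B	1.2
South	496	NAT2*12A	21
South	496	NAT2*12B	8.4
South	496	NAT2*13A	8.8
South	496	NAT2*14B	0
Total	1912	NAT2*4	20.4
Total	1912	NAT2*5A	2.1
Total	1912	NAT2*5B	29.3
Total	1912	NAT2*5C	2.8
Total	1912	NAT2*6A	17.1
Total	1912	NAT2*7B	4
Total	1912	NAT2*12A	7.4
Total	1912	NAT2*12B	2.3
Total	1912	NAT2*13A	7
Total	1912	NAT2*14B	1.5
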