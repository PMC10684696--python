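population	location	n_subjects	*4	*5	*6	*7	*12	*13	*14
Brazilian	Brazil	964	20.4	36.0	18.2	4.2	11.3	7.4	2
Ngawbe	Panama	105	72.4	2.4	0	23.3	0	1.9	ND
Embera	Panama	136	61	9.9	3.7	22.8	0	2.6	ND
Tswana	South Africa	101	13.4	32.2	20	0	20.8	6.4	8.4
San	Zimbabwe	40	23.7	20	20	1.3	23.8	2.5	8.8
Mandenka	Senegal	97	9.3	36.1	17	6.7	15.5	5.2	10.3
Sudanese	Sudan	127	8.7	47.2	28.7	3.1	8.3	0.8	3.1
Spanish	Spain	1312	22.2	45.7	26.7	1.2	2.6	0.3	1.4
French	France	60	18.3	51.7	25	0.8	0	4.2	0
German	Germany	844	22.7	46.5	27.8	1.3	ND	1.5	0.1
UK_Caucasian	United Kingdom	112	19.6	52.7	24.6	2.2	0.4	0.4	0.9
US_Caucasian	United States	387	24.2	45.9	26.6	1.9	0.4	0.9	0.1
Polish	Poland	248	22	44.4	30	3.4	0.2	0	0
Russian	Russia	364	23.5	45.6	27.2	3.2	0.5	0	0
Thai	Thailand	44	29.5	11.4	38.6	19.3	0	1.1	0
Han_Chinese	China	212	59.2	4	20.8	14.9	0.7	0.5	0
Japanese	Japan	200	69.5	0.5	19.8	8.8	ND	1.3	ND
Korean	Korea	1000	66.1	1.6	20.1	11.5	0.8	0.1	0
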