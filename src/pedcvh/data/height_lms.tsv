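sex	age_years	L	M	S
male	6.0	1.0	116.0	0.043
male	6.5	1.0	118.7875	0.043
male	7.0	1.0	121.55	0.043
male	7.5	1.0	124.2875	0.043
male	8.0	1.0	127.0	0.043
male	8.5	1.0	129.6875	0.043
male	9.0	1.0	132.35	0.043
male	9.5	1.0	134.9875	0.043
male	10.0	1.0	137.6	0.043
male	10.5	1.0	140.1875	0.043
male	11.0	1.0	142.75	0.043
male	11.5	1.0	145.2875	0.043
male	12.0	1.0	147.8	0.043
male	12.5	1.0	150.2875	0.043
male	13.0	1.0	152.75	0.043
male	13.5	1.0	155.1875	0.043
male	14.0	1.0	157.6	0.043
male	14.5	1.0	159.9875	0.043
male	15.0	1.0	162.35	0.043
male	15.5	1.0	164.6875	0.043
male	16.0	1.0	167.0	0.043
male	16.5	1.0	169.2875	0.043
male	17.0	1.0	171.55	0.043
male	17.5	1.0	173.7875	0.043
male	18.0	1.0	176.0	0.043
female	6.0	1.0	115.5	0.04
female	6.5	1.0	118.175	0.04
female	7.0	1.0	120.8	0.04
female	7.5	1.0	123.375	0.04
female	8.0	1.0	125.9	0.04
female	8.5	1.0	128.375	0.04
female	9.0	1.0	130.8	0.04
female	9.5	1.0	133.175	0.04
female	10.0	1.0	135.5	0.04
female	10.5	1.0	137.775	0.04
female	11.0	1.0	140.0	0.04
female	11.5	1.0	142.175	0.04
female	12.0	1.0	144.3	0.04
female	12.5	1.0	146.375	0.04
female	13.0	1.0	148.4	0.04
female	13.5	1.0	150.375	0.04
female	14.0	1.0	152.3	0.04
female	14.5	1.0	154.175	0.04
female	15.0	1.0	156.0	0.04
female	15.5	1.0	157.775	0.04
female	16.0	1.0	159.5	0.04
female	16.5	1.0	161.175	0.04
female	17.0	1.0	162.8	0.04
female	17.5	1.0	164.375	0.04
female	18.0	1.0	165.9	0.04
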