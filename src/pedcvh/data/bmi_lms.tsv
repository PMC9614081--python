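sex	age_years	L	M	S
male	6.0	-1.6	15.4	0.105
male	6.5	-1.59	15.578	0.1058
male	7.0	-1.58	15.762	0.1065
male	7.5	-1.57	15.952	0.1072
male	8.0	-1.56	16.148	0.108
male	8.5	-1.55	16.35	0.1088
male	9.0	-1.54	16.558	0.1095
male	9.5	-1.53	16.772	0.1102
male	10.0	-1.52	16.992	0.111
male	10.5	-1.51	17.218	0.1118
male	11.0	-1.5	17.45	0.1125
male	11.5	-1.49	17.688	0.1132
male	12.0	-1.48	17.932	0.114
male	12.5	-1.47	18.182	0.1148
male	13.0	-1.46	18.438	0.1155
male	13.5	-1.45	18.7	0.1162
male	14.0	-1.44	18.968	0.117
male	14.5	-1.43	19.242	0.1178
male	15.0	-1.42	19.522	0.1185
male	15.5	-1.41	19.808	0.1192
male	16.0	-1.4	20.1	0.12
male	16.5	-1.39	20.398	0.1208
male	17.0	-1.38	20.702	0.1215
male	17.5	-1.37	21.012	0.1222
male	18.0	-1.36	21.328	0.123
female	6.0	-1.5	15.2	0.1
female	6.5	-1.4925	15.402	0.1006
female	7.0	-1.485	15.608	0.1012
female	7.5	-1.4775	15.818	0.1018
female	8.0	-1.47	16.032	0.1024
female	8.5	-1.4625	16.25	0.103
female	9.0	-1.455	16.472	0.1036
female	9.5	-1.4475	16.698	0.1042
female	10.0	-1.44	16.928	0.1048
female	10.5	-1.4325	17.162	0.1054
female	11.0	-1.425	17.4	0.106
female	11.5	-1.4175	17.642	0.1066
female	12.0	-1.41	17.888	0.1072
female	12.5	-1.4025	18.138	0.1078
female	13.0	-1.395	18.392	0.1084
female	13.5	-1.3875	18.65	0.109
female	14.0	-1.38	18.912	0.1096
female	14.5	-1.3725	19.178	0.1102
female	15.0	-1.365	19.448	0.1108
female	15.5	-1.3575	19.722	0.1114
female	16.0	-1.35	20.0	0.112
female	16.5	-1.3425	20.282	0.1126
female	17.0	-1.335	20.568	0.1132
female	17.5	-1.3275	20.858	0.1138
female	18.0	-1.32	21.152	0.1144
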