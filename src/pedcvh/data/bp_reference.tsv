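sex	age_years	height_band	sbp_p90	sbp_p95	dbp_p90	dbp_p95
male	6	<P5	100.2	104.2	60.0	63.0
male	6	P5-P25	101.6	105.6	60.8	63.8
male	6	P25-P50	103.2	107.2	61.6	64.6
male	6	P50-P75	104.6	108.6	62.4	65.4
male	6	P75-P95	106.2	110.2	63.2	66.2
male	6	>=P95	107.6	111.6	64.0	67.0
male	7	<P5	101.3	105.3	60.8	63.8
male	7	P5-P25	102.8	106.8	61.6	64.6
male	7	P25-P50	104.3	108.3	62.4	65.4
male	7	P50-P75	105.8	109.8	63.2	66.2
male	7	P75-P95	107.3	111.3	64.0	67.0
male	7	>=P95	108.8	112.8	64.8	67.8
male	8	<P5	102.4	106.4	61.5	64.5
male	8	P5-P25	104.0	108.0	62.3	65.3
male	8	P25-P50	105.4	109.4	63.1	66.1
male	8	P50-P75	107.0	111.0	63.9	66.9
male	8	P75-P95	108.4	112.4	64.7	67.7
male	8	>=P95	110.0	114.0	65.5	68.5
male	9	<P5	103.6	107.6	62.2	65.2
male	9	P5-P25	105.1	109.1	63.0	66.0
male	9	P25-P50	106.6	110.6	63.8	66.8
male	9	P50-P75	108.1	112.1	64.6	67.6
male	9	P75-P95	109.6	113.6	65.4	68.4
male	9	>=P95	111.1	115.1	66.2	69.2
male	10	<P5	104.8	108.8	63.0	66.0
male	10	P5-P25	106.2	110.2	63.8	66.8
male	10	P25-P50	107.8	111.8	64.6	67.6
male	10	P50-P75	109.2	113.2	65.4	68.4
male	10	P75-P95	110.8	114.8	66.2	69.2
male	10	>=P95	112.2	116.2	67.0	70.0
male	11	<P5	105.9	109.9	63.8	66.8
male	11	P5-P25	107.4	111.4	64.6	67.6
male	11	P25-P50	108.9	112.9	65.4	68.4
male	11	P50-P75	110.4	114.4	66.2	69.2
male	11	P75-P95	111.9	115.9	67.0	70.0
male	11	>=P95	113.4	117.4	67.8	70.8
male	12	<P5	107.0	111.0	64.5	67.5
male	12	P5-P25	108.6	112.6	65.3	68.3
male	12	P25-P50	110.0	114.0	66.1	69.1
male	12	P50-P75	111.6	115.6	66.9	69.9
male	12	P75-P95	113.0	117.0	67.7	70.7
male	12	>=P95	114.6	118.6	68.5	71.5
male	13	<P5	108.2	112.2	65.2	68.2
male	13	P5-P25	109.7	113.7	66.0	69.0
male	13	P25-P50	111.2	115.2	66.8	69.8
male	13	P50-P75	112.7	116.7	67.6	70.6
male	13	P75-P95	114.2	118.2	68.4	71.4
male	13	>=P95	115.7	119.7	69.2	72.2
male	14	<P5	109.4	113.4	66.0	69.0
male	14	P5-P25	110.8	114.8	66.8	69.8
male	14	P25-P50	112.4	116.4	67.6	70.6
male	14	P50-P75	113.8	117.8	68.4	71.4
male	14	P75-P95	115.4	119.4	69.2	72.2
male	14	>=P95	116.8	120.8	70.0	73.0
male	15	<P5	110.5	114.5	66.8	69.8
male	15	P5-P25	112.0	116.0	67.6	70.6
male	15	P25-P50	113.5	117.5	68.4	71.4
male	15	P50-P75	115.0	119.0	69.2	72.2
male	15	P75-P95	116.5	120.5	70.0	73.0
male	15	>=P95	118.0	122.0	70.8	73.8
male	16	<P5	111.6	115.6	67.5	70.5
male	16	P5-P25	113.2	117.2	68.3	71.3
male	16	P25-P50	114.6	118.6	69.1	72.1
male	16	P50-P75	116.2	120.2	69.9	72.9
male	16	P75-P95	117.6	121.6	70.7	73.7
male	16	>=P95	119.2	123.2	71.5	74.5
male	17	<P5	112.8	116.8	68.2	71.2
male	17	P5-P25	114.3	118.3	69.0	72.0
male	17	P25-P50	115.8	119.8	69.8	72.8
male	17	P50-P75	117.3	121.3	70.6	73.6
male	17	P75-P95	118.8	122.8	71.4	74.4
male	17	>=P95	120.3	124.3	72.2	75.2
male	18	<P5	114.0	118.0	69.0	72.0
male	18	P5-P25	115.4	119.4	69.8	72.8
male	18	P25-P50	117.0	121.0	70.6	73.6
male	18	P50-P75	118.4	122.4	71.4	74.4
male	18	P75-P95	120.0	124.0	72.2	75.2
male	18	>=P95	121.4	125.4	73.0	76.0
female	6	<P5	99.2	103.2	59.5	62.5
female	6	P5-P25	100.6	104.6	60.3	63.3
female	6	P25-P50	102.2	106.2	61.1	64.1
female	6	P50-P75	103.6	107.6	61.9	64.9
female	6	P75-P95	105.2	109.2	62.7	65.7
female	6	>=P95	106.6	110.6	63.5	66.5
female	7	<P5	100.3	104.3	60.2	63.2
female	7	P5-P25	101.8	105.8	61.0	64.0
female	7	P25-P50	103.3	107.3	61.8	64.8
female	7	P50-P75	104.8	108.8	62.6	65.6
female	7	P75-P95	106.3	110.3	63.4	66.4
female	7	>=P95	107.8	111.8	64.2	67.2
female	8	<P5	101.4	105.4	61.0	64.0
female	8	P5-P25	103.0	107.0	61.8	64.8
female	8	P25-P50	104.4	108.4	62.6	65.6
female	8	P50-P75	106.0	110.0	63.4	66.4
female	8	P75-P95	107.4	111.4	64.2	67.2
female	8	>=P95	109.0	113.0	65.0	68.0
female	9	<P5	102.6	106.6	61.8	64.8
female	9	P5-P25	104.1	108.1	62.6	65.6
female	9	P25-P50	105.6	109.6	63.4	66.4
female	9	P50-P75	107.1	111.1	64.2	67.2
female	9	P75-P95	108.6	112.6	65.0	68.0
female	9	>=P95	110.1	114.1	65.8	68.8
female	10	<P5	103.8	107.8	62.5	65.5
female	10	P5-P25	105.2	109.2	63.3	66.3
female	10	P25-P50	106.8	110.8	64.1	67.1
female	10	P50-P75	108.2	112.2	64.9	67.9
female	10	P75-P95	109.8	113.8	65.7	68.7
female	10	>=P95	111.2	115.2	66.5	69.5
female	11	<P5	104.9	108.9	63.2	66.2
female	11	P5-P25	106.4	110.4	64.0	67.0
female	11	P25-P50	107.9	111.9	64.8	67.8
female	11	P50-P75	109.4	113.4	65.6	68.6
female	11	P75-P95	110.9	114.9	66.4	69.4
female	11	>=P95	112.4	116.4	67.2	70.2
female	12	<P5	106.0	110.0	64.0	67.0
female	12	P5-P25	107.6	111.6	64.8	67.8
female	12	P25-P50	109.0	113.0	65.6	68.6
female	12	P50-P75	110.6	114.6	66.4	69.4
female	12	P75-P95	112.0	116.0	67.2	70.2
female	12	>=P95	113.6	117.6	68.0	71.0
female	13	<P5	107.2	111.2	64.8	67.8
female	13	P5-P25	108.7	112.7	65.6	68.6
female	13	P25-P50	110.2	114.2	66.4	69.4
female	13	P50-P75	111.7	115.7	67.2	70.2
female	13	P75-P95	113.2	117.2	68.0	71.0
female	13	>=P95	114.7	118.7	68.8	71.8
female	14	<P5	108.4	112.4	65.5	68.5
female	14	P5-P25	109.8	113.8	66.3	69.3
female	14	P25-P50	111.4	115.4	67.1	70.1
female	14	P50-P75	112.8	116.8	67.9	70.9
female	14	P75-P95	114.4	118.4	68.7	71.7
female	14	>=P95	115.8	119.8	69.5	72.5
female	15	<P5	109.5	113.5	66.2	69.2
female	15	P5-P25	111.0	115.0	67.0	70.0
female	15	P25-P50	112.5	116.5	67.8	70.8
female	15	P50-P75	114.0	118.0	68.6	71.6
female	15	P75-P95	115.5	119.5	69.4	72.4
female	15	>=P95	117.0	121.0	70.2	73.2
female	16	<P5	110.6	114.6	67.0	70.0
female	16	P5-P25	112.2	116.2	67.8	70.8
female	16	P25-P50	113.6	117.6	68.6	71.6
female	16	P50-P75	115.2	119.2	69.4	72.4
female	16	P75-P95	116.6	120.6	70.2	73.2
female	16	>=P95	118.2	122.2	71.0	74.0
female	17	<P5	111.8	115.8	67.8	70.8
female	17	P5-P25	113.3	117.3	68.6	71.6
female	17	P25-P50	114.8	118.8	69.4	72.4
female	17	P50-P75	116.3	120.3	70.2	73.2
female	17	P75-P95	117.8	121.8	71.0	74.0
female	17	>=P95	119.3	123.3	71.8	74.8
female	18	<P5	113.0	117.0	68.5	71.5
female	18	P5-P25	114.4	118.4	69.3	72.3
female	18	P25-P50	116.0	120.0	70.1	73.1
female	18	P50-P75	117.4	121.4	70.9	73.9
female	18	P75-P95	119.0	123.0	71.7	74.7
female	18	>=P95	120.4	124.4	72.5	75.5
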