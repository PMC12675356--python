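gene_id	TR0000	TR0001	TR0002	TR0003	TR0004	TR0005	TR0006	TR0007	TR0008	TR0009	TR0010	TR0011	TR0012	TR0013	TR0014	TR0015	TR0016	TR0017	TR0018	TR0019
G00000	11.0	24.0	9.0	11.0	16.0	36.0	11.0	30.0	23.0	41.0	8.0	14.0	24.0	19.0	20.0	19.0	6.0	13.0	64.0	27.0
G00001	44.0	51.0	32.0	77.0	127.0	50.0	55.0	37.0	47.0	26.0	22.0	38.0	75.0	34.0	46.0	54.0	70.0	13.0	26.0	63.0
G00002	77.0	92.0	50.0	53.0	49.0	79.0	84.0	80.0	86.0	65.0	91.0	46.0	90.0	43.0	97.0	70.0	64.0	53.0	74.0	56.0
G00003	26.0	32.0	27.0	23.0	25.0	53.0	24.0	91.0	31.0	22.0	39.0	43.0	48.0	50.0	36.0	11.0	58.0	20.0	34.0	18.0
G00004	43.0	53.0	46.0	24.0	58.0	99.0	67.0	59.0	67.0	107.0	40.0	76.0	51.0	101.0	93.0	61.0	39.0	50.0	58.0	75.0
G00005	129.0	113.0	50.0	100.0	193.0	174.0	97.0	378.0	93.0	141.0	114.0	166.0	188.0	148.0	339.0	222.0	358.0	126.0	185.0	172.0
G00006	70.0	35.0	36.0	156.0	142.0	151.0	52.0	97.0	129.0	200.0	50.0	150.0	130.0	192.0	235.0	91.0	177.0	180.0	188.0	74.0
G00007	17.0	27.0	44.0	33.0	19.0	35.0	24.0	9.0	41.0	9.0	25.0	17.0	33.0	24.0	48.0	12.0	68.0	15.0	24.0	14.0
G00008	17.0	30.0	37.0	81.0	117.0	88.0	34.0	105.0	91.0	143.0	38.0	72.0	92.0	87.0	133.0	101.0	101.0	92.0	76.0	42.0
G00009	20.0	21.0	26.0	21.0	55.0	45.0	16.0	40.0	34.0	51.0	39.0	18.0	18.0	24.0	40.0	21.0	41.0	19.0	58.0	38.0
G00010	15.0	13.0	43.0	69.0	66.0	59.0	39.0	128.0	94.0	130.0	34.0	64.0	36.0	80.0	124.0	74.0	110.0	87.0	82.0	36.0
G00011	57.0	88.0	83.0	42.0	118.0	132.0	30.0	62.0	57.0	21.0	79.0	42.0	110.0	76.0	146.0	30.0	104.0	20.0	38.0	31.0
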