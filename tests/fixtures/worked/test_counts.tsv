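gene_id	TE0000	TE0001	TE0002	TE0003	TE0004	TE0005	TE0006	TE0007	TE0008	TE0009	TE0010	TE0011
G00000	68.0	20.0	36.0	27.0	16.0	11.0	43.0	27.0	30.0	33.0	26.0	14.0
G00001	258.0	474.0	452.0	233.0	158.0	243.0	108.0	132.0	201.0	105.0	674.0	299.0
G00002	96.0	68.0	55.0	38.0	81.0	134.0	64.0	54.0	58.0	56.0	81.0	90.0
G00003	89.0	38.0	34.0	28.0	36.0	153.0	20.0	42.0	94.0	21.0	57.0	19.0
G00004	80.0	50.0	26.0	44.0	119.0	117.0	110.0	16.0	83.0	47.0	33.0	122.0
G00005	243.0	839.0	1722.0	317.0	660.0	740.0	748.0	1725.0	703.0	288.0	217.0	403.0
G00006	235.0	121.0	104.0	160.0	205.0	259.0	286.0	192.0	142.0	70.0	136.0	224.0
G00007	42.0	16.0	18.0	12.0	77.0	10.0	20.0	28.0	14.0	22.0	24.0	24.0
G00008	95.0	57.0	90.0	75.0	120.0	101.0	106.0	94.0	64.0	30.0	112.0	74.0
G00009	43.0	11.0	37.0	16.0	49.0	38.0	20.0	19.0	29.0	17.0	46.0	39.0
G00010	138.0	93.0	82.0	135.0	101.0	70.0	166.0	84.0	50.0	22.0	77.0	46.0
G00011	39.0	46.0	38.0	122.0	75.0	60.0	35.0	38.0	112.0	140.0	47.0	118.0
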