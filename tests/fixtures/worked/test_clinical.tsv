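sample_id	recist	response	os_time	os_event
TE0000	SD	0	17.74756702758549	1
TE0001	SD	0	0.4903991647448658	1
TE0002	PD	0	4.90803680836087	1
TE0003	PD	0	23.434517692532243	0
TE0004	PD	0	2.0519916635497157	1
TE0005	SD	0	5.910505056039913	1
TE0006	PD	0	23.434517692532243	0
TE0007	PD	0	23.434517692532243	0
TE0008	SD	0	0.14251471796713125	1
TE0009	PR	1	10.565092503353736	1
TE0010	PD	0	13.13593084434706	1
TE0011	PD	0	4.89953719313479	1
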