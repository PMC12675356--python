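sample_id	recist	response	os_time	os_event
TR0000	PR	1	33.574932575091914	0
TR0001	PR	1	8.701017469696547	1
TR0002	CR	1	4.71953132115678	1
TR0003	SD	0	5.887375169674766	1
TR0004	SD	0	1.521894781823488	1
TR0005	SD	0	2.53479378008378	1
TR0006	PR	1	18.422862159169892	1
TR0007	SD	0	33.574932575091914	0
TR0008	SD	0	30.521117678519236	1
TR0009	PD	0	2.870377567925184	1
TR0010	CR	1	11.988355359103485	1
TR0011	PD	0	7.05357821455355	1
TR0012	SD	0	0.7383878480180244	1
TR0013	SD	0	33.574932575091914	0
TR0014	PD	0	0.566836444931819	1
TR0015	SD	0	25.739499270755935	1
TR0016	PD	0	2.7887971652691776	1
TR0017	PD	0	33.574932575091914	0
TR0018	PD	0	10.304187333816111	1
TR0019	CR	1	33.574932575091914	0
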