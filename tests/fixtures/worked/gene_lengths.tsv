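gene_id	length_bp
G00000	1443.0
G00001	4438.0
G00002	2379.0
G00003	1170.0
G00004	4515.0
G00005	2789.0
G00006	3890.0
G00007	1164.0
G00008	1357.0
G00009	724.0
G00010	3525.0
G00011	855.0
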