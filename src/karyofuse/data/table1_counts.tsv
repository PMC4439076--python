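group	ya	xa	wa	za	xy_systems	zw_systems	xo	zo	wo	multi_sdm	dual_fusion_zw	dual_fusion_xy
Fish	42	3	0	2	109	38	12	3	0	0	1	0
Amphibians	1	0	0	0	29	16	0	0	1	0	0	0
Reptiles	40	0	2	4	120	240	0	0	0	0	0	0
Birds	0	0	0	3	0	192	0	0	0	0	0	0
Mammals	18	24	0	0	467	0	3	0	0	8	0	2
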