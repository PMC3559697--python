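mirna	p_BD	fold_BD	p_SZ	fold_SZ
hsa-miR-15b	0.6971		0.7906
hsa-miR-29c	0.0237	2.77	0.501
hsa-miR-31	0.426		0.3699
hsa-miR-149	0.591		0.5011
hsa-miR-219	0.8723		0.4059
hsa-miR-497	0.1969		0.0026	2.35
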