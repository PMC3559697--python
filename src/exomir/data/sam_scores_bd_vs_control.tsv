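mirna	q_value_pct	local_fdr_pct
hsa-miR-219	0	27.05850719
hsa-miR-380-3p	0	28.5520989
hsa-miR-499	0	29.39061044
hsa-miR-497	0	29.86048144
hsa-miR-149	0	30.16935542
hsa-miR-501	0	32.7806583
hsa-miR-29c	0	34.68749497
hsa-miR-30e-3p	12.10826211	36.00723604
hsa-miR-504	12.10826211	37.42550117
hsa-miR-148a	12.10826211	39.79413767
hsa-miR-520a	12.10826211	41.10693353
hsa-miR-526b*	12.10826211	43.98048662
hsa-miR-15b	17.20647773	47.26654182
hsa-miR-342	17.20647773	47.55108918
hsa-miR-29b	17.20647773	49.13804596
hsa-miR-409-5p	17.20647773	50.09111912
hsa-miR-516-5p	17.20647773	50.61439857
hsa-miR-520d*	17.20647773	50.79672442
hsa-miR-500	17.20647773	50.82589406
hsa-miR-368	18.95206243	53.22108834
hsa-miR-30e-5p	18.95206243	54.66652218
hsa-miR-181c	18.95206243	55.4595906
hsa-miR-26b	18.95206243	55.51339027
hsa-miR-511	22.70299145	58.90676274
hsa-miR-527	27.24358974	63.91589056
hsa-miR-483	27.24358974	64.697843
hsa-miR-544	27.24358974	65.0689104
hsa-miR-518a-2*	27.24358974	65.91311804
hsa-miR-370	30.06189213	67.72976336
hsa-miR-100	69.07664285	70.77603166
hsa-miR-498	69.07664285	71.22258291
hsa-miR-9*	71.07023411	74.68821123
hsa-miR-125a	71.07023411	76.54730008
hsa-miR-502	72.64957265	78.54613247
hsa-miR-26a	75.17482517	84.87201631
hsa-miR-181d	77.26224393	94.90250066
hsa-miR-510	77.26224393	95.66638517
hsa-miR-512-5p	78.16485434	100
hsa-miR-299-3p	78.16485434	100
hsa-miR-142-3p	78.16485434	100
hsa-miR-148b	82.00595701	100
hsa-miR-376a	82.00595701	100
hsa-miR-302a*	82.00595701	100
hsa-miR-503	82.00595701	100
hsa-miR-202*	82.00595701	100
hsa-miR-376b	82.00595701	100
hsa-miR-200a	84.15841584	100
hsa-miR-542-3p	84.15841584	100
hsa-miR-520e	84.15841584	100
hsa-miR-516-3p	84.15841584	100
hsa-miR-302b*	84.54907162	100
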