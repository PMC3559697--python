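mirna	class_A	class_B	class_C
hsa-miR-31	-0.5474735	0.0027362
hsa-miR-33	0.6342707	-0.3112329	0.9637398
hsa-miR-96	0.040926	0.5554684
hsa-miR-28	1.1396825	1.0107414
hsa-miR-30e-5p	0.3379079
hsa-miR-199a*	-0.8762626
hsa-miR-501	0.0812317	-0.167766	-0.6013733
hsa-miR-504	0.2946595	-0.1356475	-0.3858902
hsa-miR-15b	-0.1307195
hsa-miR-29c	-0.1678	0.3820155	0.1279756
hsa-miR-455	-0.2162923	-0.2365768
hsa-miR-380-3p	-0.1295169	-0.2513642	-0.2837673
hsa-miR-323	0.0956179	-0.3292096
hsa-miR-527	0.3199353	-0.3980191	-0.4156484
hsa-miR-93	0.8926459	0.8342627	1.4247242
hsa-miR-32	-0.3081563
hsa-miR-20b	-0.3025591
hsa-miR-516-5p	0.1006308	-0.2462411	-0.4384718
hsa-miR-92	1.5916982		1.9080176
hsa-miR-30a-3p	0.2072069
hsa-miR-497	0.1045716	-0.2486034	0.036478
hsa-miR-219	0.3630727	-0.2988121
hsa-miR-499	-0.0609767	-0.3046793	-0.2561058
hsa-miR-149	0.654253	-0.2538624	0.04254
hsa-miR-30e-3p	0.4068861	-0.0672197	0.11598
hsa-miR-148a
hsa-miR-520a	-0.0963095	-1.5626633
hsa-miR-526b*	0.3595811	0.594503
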