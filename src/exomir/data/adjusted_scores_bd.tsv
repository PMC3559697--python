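mirna	z_BD	p	adj_B	p_B	adj_C	p_C	adj_BC	p_BC
hsa-miR-219	-2.8237	0.0074	-2.8237	0.0074	-3.1225	0.0030	-3.1225	0.0030
hsa-miR-380-3p	-2.2933	0.0287	-2.0419	0.0496	-2.0095	0.0529	-1.7581	0.0850
hsa-miR-499	-2.2226	0.0337	-1.9179	0.0634	-1.9665	0.0576	-1.6618	0.1002
hsa-miR-497	-2.1947	0.0358	-1.9460	0.0600	-2.2311	0.0331	-1.9825	0.0558
hsa-miR-149	-2.1785	0.0371	-1.924	0.0625	-2.2211	0.0338	-1.9672	0.0576
hsa-miR-501	-2.0751	0.0463	-1.9073	0.0647	-1.4737	0.1346	-1.3059	0.1700
hsa-miR-29c	-2.0161	0.0522	-2.3981	0.0224	-2.1440	0.0400	-2.5260	0.0164
hsa-miR-30e-3p	-1.9787	0.0563	-2.0274	0.0444	-2.0947	-1.9115	0.0641	0.0510
hsa-miR-504	-1.9404	0.0607	-1.4189	0.1191	-1.5545	-1.8048	0.0782	0.1457
hsa-miR-148a	-1.8790	0.0682	-1.8790	0.0682	-1.8790	-1.8790	0.0682	0.0682
hsa-miR-520a	-1.8457	0.0726	-0.2830	0.0726	-1.8457	-0.2830	0.3832	0.3832
hsa-miR-526b*	-1.7745	0.0826	-2.3691	0.0826	-1.7745	-2.3691	0.0241	0.0241
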