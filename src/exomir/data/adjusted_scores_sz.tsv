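mirna	z_SZ	p	adj_A	p_A	adj_B	p_B	adj_C	p_C	adj_BC	p_BC
hsa-miR-31	3.55283	0.0007	4.10031	0.00009	3.55010	0.00073	3.55283	0.00072	3.5501	0.0007
hsa-miR-33	3.10046	0.0032	2.46619	0.01906	3.41170	0.00118	2.13672	0.04069	2.4480	0.0199
hsa-miR-96	2.98240	0.0046	2.94147	0.00527	2.42693	0.02099	2.98240	0.00467	2.4269	0.0210
hsa-miR-28	2.31611	0.0272	1.17643	0.19970	1.30537	0.17017	2.31611	0.02729	1.3054	0.1702
hsa-miR-30e-5p	2.37744	0.0236	2.03954	0.04985	2.37744	0.02363	2.37744	0.02363	2.3774	0.0236
hsa-miR-199a*	2.21841	0.0340	3.09467	0.00332	2.21841	0.03406	2.21841	0.03406	2.2184	0.0341
hsa-miR-501	-1.38651	0.1525	-1.46774	0.13587	-1.21874	0.18983	-0.78514	0.29312	-0.6174	0.3297
hsa-miR-504	-1.26857	0.1784	-1.56323	0.11756	-1.13292	0.20999	-0.88268	0.27022	-0.7470	0.3018
hsa-miR-15b	1.94092	0.0606	2.07164	0.04666	1.94092	0.06066	1.94092	0.06066	1.9409	0.0607
hsa-miR-29c	-1.25599	0.1812	-1.08819	0.22068	-1.63801	0.10430	-1.38397	0.15311	-1.7660	0.0839
hsa-miR-455	1.93342	0.0615	2.14972	0.03957	2.17000	0.03788	1.93342	0.06154	2.1700	0.0379
hsa-miR-380-3p	-0.78517	0.2931	-0.65565	0.32178	-0.53381	0.34597	-0.50140	0.35182	-0.2500	0.3867
hsa-miR-323	1.79862	0.0791	1.70300	0.09357	2.12783	0.04147	1.79862	0.07915	2.1278	0.0415
hsa-miR-527	-1.15943	0.2037	-1.47937	0.13356	-0.76141	0.29855	-0.74378	0.30254	-0.3458	0.3758
hsa-miR-93	1.59984	0.1109	0.70719	0.31068	0.76558	0.29760	0.17512	0.39287	-0.6591	0.3210
hsa-miR-32	1.70564	0.09315	2.01380	0.05252	1.70564	0.09315	1.70564	0.09315	1.7056	0.0931
hsa-miR-20b	1.87742	0.06847	2.17998	0.03706	1.87742	0.06847	1.87742	0.06847	1.8774	0.0685
hsa-miR-516-5p	-0.84614	0.27890	-0.94677	0.25484	-0.59990	0.33325	-0.40767	0.36713	-0.1614	0.3938
hsa-miR-92	1.56396	0.11743	-0.02774	0.39879	1.56396	0.11743	-0.34406	0.37601	-0.3441	0.3760
hsa-miR-30a-3p	1.67931	0.09740	1.47210	0.13500	1.67931	0.09740	1.67931	0.09740	1.6793	0.0974
hsa-miR-497	-0.56728	0.33965	-0.67185	0.31834	-0.31867	0.37919	-0.60376	0.33247	-0.3551	0.3746
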