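body_site	sample_id	J	S	theta	m	logL0	logL1	q	p
Throat	700110166	506	327	399.09	0.999978	-16.98	-15.5	2.962	0.0852
Left Antecubital fossa	700102129	808	47	10.73	0.999980	-57.89	-56.6	2.594	0.1072
Left Antecubital fossa	700113117	1462	80	18.05	0.999812	-79.40	-79.9	1.078	0.2990
Right Antecubital fossa	700106174	115	81	120.54	0.999998	-9.24	-8.2	2.088	0.1485
Right Antecubital fossa	700105936	139	16	4.47	0.995735	-19.55	-20.3	1.416	0.2341
Mid vagina	700015239	12512	343	65.04	0.979742	-249.36	-251.1	3.547	0.0597
Mid vagina	700016499	25053	498	88.27	0.999139	-359.68	-358.0	3.359	0.0668
Mid vagina	700110832	4375	164	33.58	0.999910	-144.54	-144.1	0.960	0.3272
Mid vagina	700023176	5815	168	32.25	0.999892	-163.09	-163.9	1.598	0.2062
Mid vagina	700033039	4670	160	31.90	0.999952	-148.08	-148.3	0.526	0.4683
Posterior fornix	700109404	4090	174	36.77	0.997910	-140.96	-139.9	2.089	0.1484
Posterior fornix	700110833	3537	145	30.25	0.999471	-127.48	-129.3	3.672	0.0553
Posterior fornix	700024357	8120	181	32.64	0.999853	-194.34	-192.9	2.875	0.0900
Posterior fornix	700024242	7460	179	32.85	0.998841	-186.94	-185.1	3.603	0.0577
Posterior fornix	700106808	10460	288	54.50	0.999765	-228.76	-227.0	3.474	0.0623
Posterior fornix	700023398	3980	153	31.39	0.999889	-135.71	-136.9	2.352	0.1251
Posterior fornix	700015577	8946	243	46.00	0.999900	-209.83	-208.0	3.618	0.0572
Vaginal introitus	700015455	9337	294	57.53	0.999909	-213.75	-215.1	2.673	0.1021
Vaginal introitus	700023640	7943	259	51.11	0.999965	-198.53	-197.5	2.011	0.1562
Vaginal introitus	700023453	8425	242	46.41	0.999901	-202.07	-202.6	0.973	0.3240
Vaginal introitus	700114121	6847	223	44.18	0.997384	-181.00	-182.7	3.437	0.0637
Vaginal introitus	700105207	7311	218	42.08	0.999904	-188.58	-188.3	0.475	0.4906
Vaginal introitus	700109402	4418	224	49.60	0.999936	-146.13	-145.6	1.095	0.2954
Vaginal introitus	700098286	2679	223	58.57	0.902479	-109.72	-108.7	2.020	0.1553
Vaginal introitus	700097310	2277	123	27.66	0.999520	-103.66	-102.9	1.446	0.2292
Vaginal introitus	700114273	1934	195	53.86	0.999516	-89.83	-89.4	0.899	0.3431
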