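body_site	sample_id	J	S	theta	m	logL0	logL1	q	p
Anterior nares	700105415	130	93	144.71	0.999995	-8.40	-9.67	2.5417	0.1109
Stool	700106979	413	292	2029.70	0.591395	-12.16	-10.51	3.3049	0.0691
Saliva	700106858	227	144	168.36	0.999857	-12.41	-13.24	1.6687	0.1964
Saliva	700106000	161	101	183.19	0.703965	-10.93	-11.94	2.0187	0.1554
Left Antecubital fossa	700021896	377	82	32.01	0.999912	-34.90	-36.18	2.5604	0.1096
Left Antecubital fossa	700024590	173	27	8.73	0.999985	-24.35	-24.39	0.0667	0.7961
Left Antecubital fossa	700021810	364	81	31.99	0.999979	-33.97	-35.23	2.5302	0.1117
Left Retroauricular crease	700037027	110	14	4.04	0.999998	-18.16	-17.60	1.1143	0.2912
Left Retroauricular crease	700024129	199	51	21.84	0.999893	-24.01	-23.59	0.8559	0.3549
Left Retroauricular crease	700024647	174	31	10.72	0.999990	-24.40	-23.35	2.0904	0.1482
Right Antecubital fossa	700110106	165	119	190.08	0.999997	-9.16	-10.61	2.9033	0.0884
Right Antecubital fossa	700105617	128	21	14.37	0.166726	-20.11	-18.31	3.6134	0.0573
Right Antecubital fossa	700037030	114	38	19.55	0.999967	-16.44	-16.00	0.8825	0.3475
Right Antecubital fossa	700035745	329	37	10.44	0.985781	-35.34	-34.06	2.5613	0.1095
Right Antecubital fossa	700015672	331	106	53.53	0.999989	-28.24	-30.15	3.8298	0.0503
Right Antecubital fossa	700023394	382	62	20.76	0.999987	-37.39	-36.55	1.6819	0.1947
Right Antecubital fossa	700023241	922	95	26.36	0.999952	-62.30	-62.60	0.6052	0.4366
Right Retroauricular crease	700023171	641	111	38.46	0.999779	-47.49	-47.16	0.6634	0.4154
Mid vagina	700099742	4365	183	38.45	0.999805	-144.58	-146.30	3.4341	0.0639
Posterior fornix	700110242	3419	155	33.31	0.999917	-127.00	-125.46	3.0837	0.0791
Posterior fornix	700105684	3803	156	32.65	0.999534	-133.92	-132.29	3.2624	0.0709
Posterior fornix	700097502	2983	163	36.92	0.999941	-118.04	-118.87	1.6699	0.1963
Posterior fornix	700099080	5079	175	34.93	0.999892	-155.68	-156.69	2.0075	0.1565
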