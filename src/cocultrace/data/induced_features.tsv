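mz	rt_min	polarity	formula	class	fold_ratio	fold_sd	producer	coculture_intensity
136.0403	3.91	neg	C7H7NO2	newly_synthesized			B	40000
165.0554	9.79	neg	C9H10O3	fold_increased	15.8	0.7	both	25000
166.0507	8.65	neg	C8H9NO3	newly_synthesized			none	60000
167.0348	9.90	neg	C8H8O4	fold_increased	5.8	0.6	B	5000
181.0615	6.46	neg	C8H10N2O3	newly_synthesized			A	4000
195.0505	8.37	neg	C6H12O4	fold_increased	25.3	1.2	none	
244.0612	6.86	neg	C13H11NO4	newly_synthesized			none	7000
249.1497	16.33	neg	C15H22O3	newly_synthesized			A	15000
251.0712	15.72	neg	C16H12O3	fold_increased	7.3	1.3	A	6000
269.0577	11.75	neg	C14H10N2O4	newly_synthesized			B	9000
271.0716	7.03	neg	C14H12N2O4	newly_synthesized			B	100000
271.0725	10.25	neg	C14H12N2O4	newly_synthesized			B	70000
279.0656	13.25	neg	C17H12O4	fold_increased	5.2	1.3	A	250000
281.0808	11.93	neg	C17H14O4	fold_increased	102.2	4.8	A	50000
298.0928	8.65	neg	C13H17NO7	newly_synthesized			none	23000
304.0626	3.33	neg	C9H13N3O9	newly_synthesized			none	
306.0775	10.46	neg	C18H13NO4	newly_synthesized			none	
309.0756	12.04	neg	C18H14O5	fold_increased	15.4	1.2	both	250000
311.0931	11.49	neg	C18H16O5	fold_increased	400	7.1	A	40000
314.0899	3.32	neg	C14H13N5O4	newly_synthesized			none	
330.2656	14.03	neg	C18H37NO4	fold_increased	59.7	8.1	A	60000
334.0733	11.44	neg	C20H9N5O4	newly_synthesized			none	
337.0712	10.59	neg	C20H10N4O2	newly_synthesized			none	
341.1046	16.16	neg	C20H14N4O2	newly_synthesized			A	5000
342.2654	15.17	neg	C19H37NO4	newly_synthesized			both	60000
387.1926	20.12	neg	C19H36N2S3	newly_synthesized			none	
389.2072	20.07	neg	C19H38N2S3	newly_synthesized			none	
397.223	19.42	neg	C21H34O7	newly_synthesized			none	12500
398.1058	13.53	neg	C25H13N5O	newly_synthesized			none	
399.2386	20.07	neg	C21H36O7	fold_increased	103.3	4.2	none	3000
405.0737	12.83	neg	C22H10N6O3	newly_synthesized			none	
406.1043	7.89	neg	C22H13N7O2	newly_synthesized			none	
415.2338	10.40	neg	C21H36O8	newly_synthesized			none	
436.2698	15.86	neg	C24H39NO6	newly_synthesized			A	25000
454.2817	15.86	neg	C24H41NO7	newly_synthesized			A	15000
455.1685	8.64	neg	C21H24N6O6	newly_synthesized			none	
472.2923	15.86	neg	C24H43NO8	newly_synthesized			A	12500
490.3025	15.06	neg	C24H45NO9	newly_synthesized			A	34000
567.3139	15.87	neg	C25H48N2O12	newly_synthesized			A	7000
581.1208	13.24	neg	C36H22O8	newly_synthesized			none	
586.2857	16.44	neg	C28H45NO12	newly_synthesized			none	2000
597.1968	8.63	neg	C31H34O12	newly_synthesized			none	
629.1419	11.77	neg	C30H22N4O12	newly_synthesized			none	
641.1461	12.65	neg	C19H29N7O18	newly_synthesized			none	
138.0555	3.93	pos	C7H7NO2	newly_synthesized			B	80000
140.0708	8.64	pos	C7H9NO2	fold_increased	14.9	1.3	B	11000
150.0548	8.53	pos	C8H7NO2	newly_synthesized			none	100000
160.0377	3.84	pos	C4H5N3O4	newly_synthesized			none	
168.0653	8.65	pos	C8H9NO3	newly_synthesized			none	80000
196.0944	9.16	pos	C10H13NO3	newly_synthesized			none	2000
216.1021	14.2	pos	C13H14NO2	newly_synthesized			none	10000
230.1177	19.07	pos	C14H15NO2	newly_synthesized			none	2600
257.0919	9.18	pos	C14H12N2O3	newly_synthesized			none	
265.0860	11.92	pos	C17H12O3	fold_increased	802.4	9.6	none	
268.2277	15.96	pos	C16H29NO2	newly_synthesized			none	4000
270.0979	3.27	pos	C13H11N5O2	newly_synthesized			none	
272.1129	3.58	pos	C12H17NO6	newly_synthesized			none	
273.0871	10.22	pos	C14H12N2O4	newly_synthesized			B	110000
286.1436	14.85	pos	C17H19NO3	newly_synthesized			none	
287.1030	10.61	pos	C16H10N6	newly_synthesized			none	
288.2900	20.88	pos	C17H37NO2	fold_increased	50.5	3.3	A	19000
298.2744	18.56	pos	C18H35NO2	newly_synthesized			A	40000
300.1076	8.65	pos	C13H17NO7	newly_synthesized			none	30000
302.3069	21.38	pos	C18H39NO2	fold_increased	24.4	3.1	both	480000
322.0898	8.7	pos	C11H11N7O5	newly_synthesized			none	
330.3371	26.77	pos	C20H43NO2	fold_increased	152.3	1.6	A	5600
332.2800	14.05	pos	C18H37NO4	fold_increased	74.3	4.6	A	36000
334.2953	14.95	pos	C18H39NO4	newly_synthesized			A	16000
344.2803	15.17	pos	C19H37NO4	newly_synthesized			both	125000
348.1430	11.71	pos	C20H17N3O3	newly_synthesized			none	
358.2955	15.66	pos	C20H39NO4	fold_increased	25.2	2.3	A	30000
369.2269	13.47	pos	C16H28N6O4	newly_synthesized			none	
372.3113	19.96	pos	C21H41NO4	newly_synthesized			both	360000
377.2302	20.09	pos	C18H28N6O3	newly_synthesized			none	
400.1019	7.96	pos	C17H9N11O2	newly_synthesized			none	
432.1504	8.68	pos	C19H21N5O7	newly_synthesized			none	
474.3068	15.86	pos	C24H43NO8	newly_synthesized			A	12500
492.3176	15.04	pos	C24H45NO9	newly_synthesized			A	15000
496.2886	16.43	pos	C15H41N2O4	newly_synthesized			A	40000
506.3332	15.85	pos	C25H47NO9	newly_synthesized			A	30000
599.2043	8.63	pos	C31H34O12	newly_synthesized			none	
716.5259	18.91	pos	C42H69NO8	newly_synthesized			none	
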