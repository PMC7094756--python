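index	name
1	Precentral_L
2	Precentral_R
3	Frontal_Sup_2_L
4	Frontal_Sup_2_R
5	Frontal_Mid_2_L
6	Frontal_Mid_2_R
7	Frontal_Inf_Oper_L
8	Frontal_Inf_Oper_R
9	Frontal_Inf_Tri_L
10	Frontal_Inf_Tri_R
11	Frontal_Inf_Orb_2_L
12	Frontal_Inf_Orb_2_R
13	Rolandic_Oper_L
14	Rolandic_Oper_R
15	Supp_Motor_Area_L
16	Supp_Motor_Area_R
17	Olfactory_L
18	Olfactory_R
19	Frontal_Sup_Medial_L
20	Frontal_Sup_Medial_R
21	Frontal_Med_Orb_L
22	Frontal_Med_Orb_R
23	Rectus_L
24	Rectus_R
25	OFCmed_L
26	OFCmed_R
27	OFCant_L
28	OFCant_R
29	OFCpost_L
30	OFCpost_R
31	OFClat_L
32	OFClat_R
33	Insula_L
34	Insula_R
35	Cingulate_Ant_L
36	Cingulate_Ant_R
37	Cingulate_Mid_L
38	Cingulate_Mid_R
39	Cingulate_Post_L
40	Cingulate_Post_R
41	Hippocampus_L
42	Hippocampus_R
43	ParaHippocampal_L
44	ParaHippocampal_R
45	Amygdala_L
46	Amygdala_R
47	Calcarine_L
48	Calcarine_R
49	Cuneus_L
50	Cuneus_R
51	Lingual_L
52	Lingual_R
53	Occipital_Sup_L
54	Occipital_Sup_R
55	Occipital_Mid_L
56	Occipital_Mid_R
57	Occipital_Inf_L
58	Occipital_Inf_R
59	Fusiform_L
60	Fusiform_R
61	Postcentral_L
62	Postcentral_R
63	Parietal_Sup_L
64	Parietal_Sup_R
65	Parietal_Inf_L
66	Parietal_Inf_R
67	SupraMarginal_L
68	SupraMarginal_R
69	Angular_L
70	Angular_R
71	Precuneus_L
72	Precuneus_R
73	Paracentral_Lobule_L
74	Paracentral_Lobule_R
75	Caudate_L
76	Caudate_R
77	Putamen_L
78	Putamen_R
79	Pallidum_L
80	Pallidum_R
81	Thalamus_L
82	Thalamus_R
83	Heschl_L
84	Heschl_R
85	Temporal_Sup_L
86	Temporal_Sup_R
87	Temporal_Pole_Sup_L
88	Temporal_Pole_Sup_R
89	Temporal_Mid_L
90	Temporal_Mid_R
91	Temporal_Pole_Mid_L
92	Temporal_Pole_Mid_R
93	Temporal_Inf_L
94	Temporal_Inf_R
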