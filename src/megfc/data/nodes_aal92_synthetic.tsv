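index	name	x	y	z	is_seed
0	Precentral_L	-39	-6	51	0
1	Precentral_R	41	-8	52	0
2	Frontal_Sup_L	-18	35	42	1
3	Frontal_Sup_R	22	31	44	0
4	Frontal_Sup_Orb_L	-17	47	-13	0
5	Frontal_Sup_Orb_R	18	48	-14	0
6	Frontal_Mid_L	-33	33	35	0
7	Frontal_Mid_R	38	33	34	0
8	Frontal_Mid_Orb_L	-31	50	-10	1
9	Frontal_Mid_Orb_R	33	53	-11	0
10	Frontal_Inf_Oper_L	-48	13	19	1
11	Frontal_Inf_Oper_R	50	15	21	0
12	Frontal_Inf_Tri_L	-46	30	14	0
13	Frontal_Inf_Tri_R	50	30	14	0
14	Frontal_Inf_Orb_L	-36	31	-12	0
15	Frontal_Inf_Orb_R	41	32	-12	0
16	Rolandic_Oper_L	-47	-8	14	0
17	Rolandic_Oper_R	53	-6	15	0
18	Supp_Motor_Area_L	-5	5	61	1
19	Supp_Motor_Area_R	9	0	62	0
20	Olfactory_L	-8	15	-11	0
21	Olfactory_R	10	16	-11	0
22	Frontal_Sup_Medial_L	-5	49	31	0
23	Frontal_Sup_Medial_R	9	51	30	0
24	Frontal_Med_Orb_L	-5	54	-7	0
25	Frontal_Med_Orb_R	8	52	-7	0
26	Rectus_L	-5	37	-18	0
27	Rectus_R	8	36	-18	0
28	Insula_L	-35	7	3	1
29	Insula_R	39	6	2	0
30	Cingulum_Ant_L	-4	35	14	0
31	Cingulum_Ant_R	8	37	16	1
32	Cingulum_Mid_L	-5	-15	42	0
33	Cingulum_Mid_R	8	-9	40	0
34	Cingulum_Post_L	-5	-43	25	0
35	Cingulum_Post_R	7	-42	22	0
36	Hippocampus_L	-25	-21	-10	0
37	Hippocampus_R	29	-20	-10	0
38	ParaHippocampal_L	-21	-16	-21	0
39	ParaHippocampal_R	25	-15	-20	0
40	Amygdala_L	-23	-1	-17	0
41	Amygdala_R	27	1	-18	0
42	Calcarine_L	-7	-79	6	0
43	Calcarine_R	16	-73	9	0
44	Cuneus_L	-6	-80	27	0
45	Cuneus_R	14	-79	28	0
46	Lingual_L	-15	-68	-5	0
47	Lingual_R	16	-67	-4	0
48	Occipital_Sup_L	-17	-84	28	0
49	Occipital_Sup_R	24	-81	31	0
50	Occipital_Mid_L	-32	-81	16	0
51	Occipital_Mid_R	37	-80	19	0
52	Occipital_Inf_L	-36	-78	-8	0
53	Occipital_Inf_R	38	-82	-8	0
54	Fusiform_L	-31	-40	-20	0
55	Fusiform_R	34	-39	-20	0
56	Postcentral_L	-42	-23	49	0
57	Postcentral_R	41	-25	53	0
58	Parietal_Sup_L	-23	-60	59	0
59	Parietal_Sup_R	26	-59	62	0
60	Parietal_Inf_L	-43	-46	47	0
61	Parietal_Inf_R	46	-46	50	0
62	SupraMarginal_L	-56	-34	30	0
63	SupraMarginal_R	58	-32	34	0
64	Angular_L	-44	-61	36	0
65	Angular_R	46	-60	39	0
66	Precuneus_L	-7	-56	48	1
67	Precuneus_R	10	-56	44	0
68	Paracentral_Lobule_L	-8	-25	70	0
69	Paracentral_Lobule_R	7	-32	68	0
70	Caudate_L	-11	11	9	1
71	Caudate_R	15	12	9	0
72	Putamen_L	-24	4	2	1
73	Putamen_R	28	5	2	1
74	Pallidum_L	-18	0	0	0
75	Pallidum_R	21	0	0	0
76	Thalamus_L	-11	-18	8	1
77	Thalamus_R	13	-18	8	0
78	Heschl_L	-42	-19	10	0
79	Heschl_R	46	-17	10	0
80	Temporal_Sup_L	-53	-21	7	0
81	Temporal_Sup_R	58	-22	7	0
82	Temporal_Pole_Sup_L	-40	15	-20	0
83	Temporal_Pole_Sup_R	48	15	-17	0
84	Temporal_Mid_L	-56	-34	-2	0
85	Temporal_Mid_R	57	-37	-1	0
86	Temporal_Pole_Mid_L	-36	15	-34	0
87	Temporal_Pole_Mid_R	44	15	-32	1
88	Temporal_Inf_L	-50	-28	-23	0
89	Temporal_Inf_R	54	-31	-22	0
90	Accumbens_L	-9	11	-7	1
91	Accumbens_R	9	11	-7	0
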