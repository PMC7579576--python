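roi_index	region_name	subnetwork
59	Parietal_Sup_L	DMN
60	Parietal_Sup_R	DMN
61	Parietal_Inf_L	DMN
62	Parietal_Inf_R	DMN
85	Temporal_Mid_L	DMN
86	Temporal_Mid_R	DMN
29	Insula_L	DMN-anterior
30	Insula_R	DMN-anterior
31	Cingulum_Ant_L	DMN-anterior
32	Cingulum_Ant_R	DMN-anterior
87	Temporal_Pole_Mid_L	DMN-anterior
88	Temporal_Pole_Mid_R	DMN-anterior
35	Cingulum_Post_L	DMN-ventral
36	Cingulum_Post_R	DMN-ventral
37	Hippocampus_L	DMN-ventral
38	Hippocampus_R	DMN-ventral
39	ParaHippocampal_L	DMN-ventral
40	ParaHippocampal_R	DMN-ventral
55	Fusiform_L	DMN-ventral
56	Fusiform_R	DMN-ventral
65	Angular_L	DMN-ventral
66	Angular_R	DMN-ventral
67	Precuneus_L	DMN-ventral
68	Precuneus_R	DMN-ventral
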