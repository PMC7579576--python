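indicator	n_ds	mean_rank_ds	n_control	mean_rank_control	printed_significance
Global Clustering Coefficient	10	21.80	22	14.09	0.015
Number of Triangles	22	20.77	22	24.23	0.186
Modularity	22	21.41	22	23.59	0.286
Characteristic Path Length	22	14.73	22	30.27	<0.001
Mean Path Length	22	20.18	22	24.82	0.115
SD Path Length	22	26.73	22	18.27	0.014
Complexity	22	27.14	22	17.86	0.008
Small-Worldness	22	19.23	22	25.77	0.045
Degree	22	23.23	22	21.77	0.353
Dunn Index	22	32.50	22	12.50	<0.001
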