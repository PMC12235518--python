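gene	direction	log2FC	q	delta_betweenness	delta_eigenvector	rank_b	rank_e	norm_b	norm_e	ensemble_score	excluded	exclusion_reason	final_rank
G05	down	-1.0531395844222242	3.7929512633818704e-05	0.06666666666666667	0.11612754560426664	1.5	2.0	0.9166666666666666	0.8333333333333334	0.7638888888888888	False		1.0
G01	down	-0.4286087279807367	0.012793098102273094	0.06666666666666665	0.04773795573165035	3.0	5.0	0.6666666666666666	0.3333333333333333	0.2222222222222222	False		2.0
G04	down	-0.9151754772266125	0.0005820527225505642	0.0	0.11163203689578047	5.5	3.0	0.25	0.6666666666666666	0.16666666666666666	False		3.0
G09	down	-1.3433163413014686	8.7041616708088e-05	0.06666666666666667	0.03739595961575054	1.5	6.0	0.9166666666666666	0.16666666666666666	0.15277777777777776	False		4.0
G14	up	0.46057051144201466	0.048980777520973344	0.0	0.10325289908292018	5.5	4.0	0.25	0.5	0.125	False		5.0
G07	down	-0.03093955324500186	0.9360609486475326	0.0	0.1534763372664178	5.5	1.0	0.25	1.0	0.25	True	below mean for all measures in all conditions	
G17	up	1.0274808502602326	2.5939696512134017e-06	0.0	0.0013608863711547792	5.5	7.0	0.25	0.0	0.0	True	below mean for all measures in all conditions	
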