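# source: published threshold table, lambda_k for three patients (columns 1-2: N=1e10, column 3: N=1e9)
k	lambda_k1	lambda_k2	lambda_k3
1	1e-10	1e-10	1e-09
2	1.41e-05	1.41e-05	5e-05
3	0.000843	0.000843	0.00181
4	0.006999	0.006999	0.0124
5	0.0260517	0.02605	0.04128
6	0.064499	0.0644	0.0946
7	0.12599	0.12599	0.175
8	0.211684	0.2116	0.282
9	0.3211	0.3211	0.415
10	0.45287	0.45287	0.57
11	0.60523	0.60523	0.746
12	0.776297	0.776297	0.94
13	0.9642	0.9642	1.15
14	1.16727	1.16727	
15	1.38388	1.38388	
16	1.61264	1.61264	
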