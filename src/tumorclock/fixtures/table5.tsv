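# source: published driver count k, time required (years) and number of cancer cells (NCCs) for the two colorectal patients
patient	k	time_required_years	nccs
Mx34	8	13	6800
Mx34	11	16.6	2000000
Mx34	15	19.4	100000000
Mx34	19	21.3	1000000000
Mx34	26	23.5	5500000000
Mx34	30	24.4	8000000000
Mx34	33	25	9000000000
Co82	2	11	6.8
Co82	3	18	300
Co82	4	22	10000
Co82	5	25	100000
Co82	7	28	800000
Co82	8	30	10000000
Co82	11	36	50000000
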