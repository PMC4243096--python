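# source: published estimates of mutation count (NMs), initial mutation rate and selective advantage for seven pancreatic-cancer patients
patient	nms	mu0	s
Pa01c	49	5e-05	0.007
Pa02c	35	9e-05	0.008
Pa03c	28	6e-04	0.014
Pa04c	34	9e-05	0.008
Pa05c	28	4e-04	0.01
Pa07c	50	2.5e-04	0.008
Pa08c	35	5e-05	0.007
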