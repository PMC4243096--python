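# source: published per-patient parameters; mu0_body_text/b_body_text transcribe the conflicting body-text rate curves mu(t)=2e-5*exp(0.0032 t) and mu(t)=1e-7*exp(0.0016 t)
# note: t_k unit and definition unstated in the source
patient	s	mu0	a	t_k	mu0_body_text	b_body_text
Mx34	0.01	2e-05	0.316	3165	2e-05	0.0032
Co82	0.0075	2e-07	0.309	3150	1e-07	0.0016
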