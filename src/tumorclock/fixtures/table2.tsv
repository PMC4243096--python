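# source: published stage timeline for patient Mx34 (waiting time WT in years, number of mutations NM); ranges kept verbatim as strings
stage	wt_model	wt_published	nm_model	nm_published
microadenoma	1-2	3	3	3
small_adenoma	3-4	5	4	4
large_adenoma	7	7	5	5
early_carcinoma	8-19	8-23	6-25	6-25
advanced_carcinoma	20-30	25	>25	>25
metastasis	33	25	>33	28
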