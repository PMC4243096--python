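# source: published stage timeline for patient Co82 (time required in years); ranges kept verbatim as strings
stage	time_required_years	k
microadenoma	11	3
small_adenoma	18	4
large_adenoma	22	5
carcinoma	27-33	6-11
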