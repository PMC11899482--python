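subtype	n_patients	gvhd
acute_only	12	yes
late_acute	3	yes
overlap_syndrome	1	yes
acute_and_chronic	5	yes
chronic_only	5	yes
none	5	no
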