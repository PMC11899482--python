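patient_id	span_days	n_samples	group	max_grade	infections	relapse
BZP1	306	25	aGVHD	aGVHD I	RSV + FLU; CMV	no
BZP3	119	15	aGVHD	aGVHD III	TBC; Pseudom. A.	no
FHP26	290	19	aGVHD	aGVHD II	Suspected bacterial; Parainflu.	no
FHP38	188	17	aGVHD	aGVHD III	Clostr. Diff.	no
FHP42	95	10	aGVHD	aGVHD II	FUO; CMV	no
FHP34	215	16	aGVHD	aGVHD III	CMV; E. Coli	yes (d214)
FHP6	281	24	aGVHD and cGVHD	aGVHD II, cGVHD moderate	no	no
FHP1	244	16	aGVHD and cGVHD	aGVHD II, cGVHD mild	FUO	yes (d315)
FHP11	324	14	aGVHD and cGVHD	aGVHD III, cGVHD mild	Parainflu.; Clostr. Diff.	yes (d157)
FHP4	430	33	aGVHD and cGVHD	aGVHD III, cGVHD moderate	CMV; Parainflu.	yes (d445)
BZP5	70	8	aGVHD and cGVHD	aGVHD II, chronic mod/sev	EBV + bacterial infection	no
BZP2	273	19	NO GVHD	none	no	no
FHP32	78	8	NO GVHD	none	no	no
FHP44	160	18	NO GVHD	none	no	no
FHP46	73	3	NO GVHD	none	no	no
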