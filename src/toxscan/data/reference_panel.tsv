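phosphatase	accession	oa_ic50	reported_class	site1	site2	site3	site4	site5	site6	site7	site8	site9	site10	inserts
PP1-arch2	O34200	500	ModeratelySensitive	R	M	Y	W	R	A	Y	V	-	L
PP1	P36873	15-50	Sensitive	R	I	Y	W	R	V	Y	C	E	F
BSU1	Q9LR78	15-50	Sensitive	R	M	Y	W	R	C	Y	C	T	A
PP2A	P67775	0.1	Sensitive	R	I	Y	W	R	L	Y	C	R	C
PP2B	Q08209	>1000	Insensitive	R	L	F	W	R	A	Y	L	V	Y
PP7	Q9FN02	20000	GrosslyInsensitive	R	C	Y	W	R	G	Y	E	R	Y	5:12,7:6
PP5	P53041	~1	Sensitive	R	M	Y	W	R	V	Y	C	Q	M
PPEF1	O14829	>1000	Insensitive	R	M	Y	W	R	C	Y	Y	E	G
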