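protein	mutation	disease	location	defect	motif	prior_structural_ref	variant_type
AQP2	L22V	NDI	H1	tetramer assembly		none	disease
AQP2	L28P	NDI	H1	monomer folding		none	disease
AQP2	A47V	NDI	H2	monomer folding		none	disease
AQP2	Q57P	NDI	H2	impaired metal binding		frick2014	disease
AQP2	G64R	NDI	H2	pore features		none	disease
AQP2	N68S	NDI	HB	pore features	NPA	frick2014	disease
AQP2	A70D	NDI	HB	pore features	NPA	frick2014	disease
AQP2	V71M	NDI	HB	pore features		frick2014	disease
AQP2	G100R	NDI	H3	monomer folding		frick2014	disease
AQP2	G100V	NDI	H3	monomer folding		none	disease
AQP2	T108M	NDI	H3	monomer folding		none	disease
AQP2	T125M	NDI	loop C	tetramer assembly		frick2014	disease
AQP2	T126M	NDI	H4	tetramer assembly		frick2014	disease
AQP2	A147T	NDI	H4	impaired metal binding		frick2014	disease
AQP2	V168M	NDI	H5	pore features		frick2014	disease
AQP2	G175R	NDI	H5	monomer folding		none	disease
AQP2	G180S	NDI	H5	pore features		none	disease
AQP2	C181W	NDI	loop E	monomer folding		none	disease
AQP2	P185A	NDI	HE	pore features	NPA	frick2014	disease
AQP2	R187C	NDI	HE	pore features	ar/R	frick2014	disease
AQP2	R187H	NDI	HE	pore features	ar/R	frick2014	disease
AQP2	A190T	NDI	HE	monomer folding		none	disease
AQP2	W202C	NDI	H6	monomer folding		none	disease
AQP2	S216P	NDI	H6	monomer folding		none	disease
AQP2	R254L	NDI	C-ter	signal loss		functional-only	disease
AQP2	R254Q	NDI	C-ter	signal loss		functional-only	disease
AQP2	E258K	NDI	C-ter	signal loss		functional-only	disease
AQP2	P262L	NDI	C-ter	signal loss		functional-only	disease
AQP5	A38E	PPKB	loop A	tetramer assembly		aqp5study	disease
AQP5	I45S	PPKB	H2	pore features		aqp5study	disease
AQP5	N123D	PPKB	loop C	tetramer assembly		aqp5study	disease
AQP5	I177F	PPKB	H5	pore features		aqp5study	disease
AQP5	R188C	PPKB	HE	pore features		aqp5study	disease
AQP8	I229M	colorectal tumor	H6	monomer folding		none	unclassified
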