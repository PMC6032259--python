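protein	residue_range	pdb_id	mutation	asymmetric_unit	pore	method	resolution	deposition
AQP1	8-233	1FQY	--	monomer	--	EC	3.80	2000
AQP1	9-233	1H6I	--	monomer	--	EC	3.80	2001
AQP1	9-232	1IH5	--	monomer	--	EC	3.70	2001
AQP1	3-235	4CSK	--	monomer	--	XRD	3.28	2014
AQP2	2-240	4NEF	--	tetramer	--	XRD	2.75	2013
AQP2	5-257	4OJ2	S256A	monomer	water	XRD	3.05	2014
AQP4	32-254	3GD8	--	monomer	water	XRD	1.80	2009
AQP5	1-245	3D9S	--	tetramer	water	XRD	2.00	2008
AQP5	2-245	5C5X	S156E	octamer	water	XRD	2.60	2015
AQP5	2-244	5DYE	S156E	tetramer	--	XRD	3.50	2015
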