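# Synthetic 51-position pore-lining mapping for human AQP2 (stand-in).
# This file is a constructed surrogate, NOT a transcription of a published
# mapping: only the anchor pairs below are documented residue/position
# statements for AQP2; the remaining rows are plausible filler chosen so
# that positions are contiguous from 1 (cytoplasmic side first) and all
# residue numbers are distinct and within the AQP2 transmembrane region.
# Anchors: 10->G64, 21->V71, 23->N68, 26->V168, 30->R187 (ar/R),
#          36->C181, 41->G180.
# alignment_column refers to an ungapped toy reference alignment.
position	aqp2_residue	alignment_column
1	88	88
2	60	60
3	92	92
4	63	63
5	95	95
6	84	84
7	67	67
8	91	91
9	99	99
10	64	64
11	96	96
12	103	103
13	73	73
14	100	100
15	77	77
16	107	107
17	80	80
18	104	104
19	111	111
20	74	74
21	71	71
22	115	115
23	68	68
24	119	119
25	164	164
26	168	168
27	123	123
28	160	160
29	127	127
30	187	187
31	171	171
32	124	124
33	156	156
34	131	131
35	175	175
36	181	181
37	128	128
38	152	152
39	135	135
40	176	176
41	180	180
42	148	148
43	139	139
44	172	172
45	132	132
46	144	144
47	196	196
48	192	192
49	200	200
50	204	204
51	208	208
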