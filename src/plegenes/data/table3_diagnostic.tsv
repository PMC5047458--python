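position	gamma-PLE	PLE2	PLE3	PLE4	PLE5	PLE6	APLE	PLE-1	PLE-B9	PLE-C4	PLE-G2
73	D	D	E	D	D	E	E	D	D	E	D
75	V	V	I	V	V	I	I	V	I	I	V
76	V	V	G	A	A	G	G	V	G	G	A
77	E	E	G	G	G	G	G	E	E	E	G
80	T	T	L	T	T	L	L	T	L	L	T
87	G	G	R	R	R	R	R	G	R	R	G
92	T	T	I	I	I	I	I	T	I	T	I
93	L	L	P	P	P	P	P	L	P	P	P
129	L	L	V	V	V	V	V	L	V	V	V
133	P	P	S	S	S	S	S	P	S	S	S
134	M	M	T	T	T	T	T	M	T	T	T
138	V	V	L	L	L	L	L	V	L	L	L
139	V	V	A	A	A	A	A	V	A	A	A
234	L	L	F	F	F	F	F	L	F	L	L
236	V	V	A	A	A	A	A	V	A	A	V
237	A	A	G	G	G	G	G	A	A	A	A
285	F	F	P	P	F	F	F	F	F	F	F
286	L	L	L	L	F	F	F	L	F	F	L
287	T	T	T	T	A	A	A	T	A	A	T
290	F	F	L	L	L	L	L	F	L	L	F
294	Q	Q	P	P	P	P	P	Q	P	P	Q
302	P	P	T	T	T	T	T	P	T	T	T
459	F	A	F	A	A	A	F	F	A	A	F
461	L	F	L	F	F	F	L	L	F	F	L
463	K	R	K	R	R	R	K	K	R	K	K
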