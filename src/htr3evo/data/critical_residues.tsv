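position	aa	region	role	ligand	note
34	N	pre_loop	glycosylation	none	
83	N	pre_loop	glycosylation	none	
91	W	loopD	ligand binding	granisetron	
93	R	loopD	ligand binding	granisetron	
95	Y	loopD	ligand binding	granisetron	
108	F	post_loopD	ligand binding	5-HT	
119	D	loopA	conductance	none	
130	E	loopA	ligand binding	5-HT	
131	F	loopA	ligand binding	5-HT	
132	V	loopA	loop structure	none	
133	D	loopA	conductance	none	
144	Y	loopE	ligand binding	granisetron	
149	G	loopE	ligand binding	granisetron	
151	V	loopE	ligand binding	granisetron	
154	Y	loopE	ligand binding	5-HT	
156	P	post_loopE	pore-opening proline	none	
163	C	cys_loop	disulfide	none	
166	D	cys_loop	loop structure	none	
167	I	cys_loop	loop structure	none	
168	Y	cys_loop	loop structure	none	
170	F	cys_loop	loop structure	none	
171	P	cys_loop	pore-opening proline	granisetron	
172	F	cys_loop	loop structure	none	
173	D	cys_loop	loop structure	none	
176	N	cys_loop	glycosylation	none	
177	C	cys_loop	disulfide	none	
179	L	loopB	loop structure	granisetron	
180	T	loopB	loop structure	granisetron	
181	F	loopB	loop structure	granisetron	
183	S	loopB	loop structure	granisetron	
184	W	loopB	ligand binding	mCPBG	
191	I	loopB	loop structure	granisetron	
192	N	loopB	glycosylation	none	
196	W	loopF	ligand binding	granisetron	
205	D	loopF	ligand binding	granisetron	
227	F	loopC	ligand binding	5-HT	
228	S	loopC	ligand binding	granisetron	
229	M	loopC	ligand binding	granisetron	
235	Y	loopC	ligand binding	granisetron	sometimes cited as Y234
237	E	loopC	ligand binding	granisetron	
258	P	TM1	pore	none	
273	P	post_TM1	pore-opening proline	none	
274	P	post_TM1	pore-opening proline	none	
281	S	TM2	pore	none	
287	L	TM2	pore	none	
288	L	TM2	pore	none	
293	F	TM2	pore	none	
299	D	TM2	pore	none	
334	R	TM3	structure	none	
341	L	ICL	RIC-3 context	none	
432	R	ICL	conductance	none	
438	R	ICL	conductance	none	
442	R	ICL	conductance	none	
446	R	ICL	conductance	none	
459	L	TM4	structure	none	
460	F	TM4	structure	none	
466	A	TM4	structure	none	
470	Y	TM4	structure	none	
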