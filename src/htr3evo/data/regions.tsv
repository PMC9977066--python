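name	start	end	category
signal_peptide	1	21	extracellular
ligand_binding_span	87	239	extracellular
loopD	87	97	extracellular
loopA	117	133	extracellular
loopE	140	155	extracellular
cys_loop	163	177	extracellular
loopB	175	192	extracellular
loopF	193	207	extracellular
loopC	225	239	extracellular
TM1	252	272	transmembrane
TM2	279	299	transmembrane
TM3	318	338	transmembrane
ICL	341	455	intracellular
ric3_region	341	364	intracellular
TM4	457	478	transmembrane
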