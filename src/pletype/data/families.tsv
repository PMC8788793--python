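family	peptide_length	macrocycle_size	targeted	clade	note
Factin	8	Linear	false	Factin
Bananamide	8	6	true	Bananamide
Viscosin	9	7	false	Viscosin
Orfamide	10	8	false	Orfamide
Poaeamide	10	8	false	Poaeamide
Amphisin	11	9	true	Amphisin
Gacamide	11	5	true	Gacamide
Putisolvin	12	4	true	Putisolvin
Xantholysin	14	8	true	Xantholysin-Entolysin
Entolysin	14	5	true	Xantholysin-Entolysin
Tolaasin	18	5	true	Tolaasin
Peptin	22	8	false	Peptin	member lengths span 19-25 with macrocycles 5-8 or linear; profile follows syringopeptin SP22
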