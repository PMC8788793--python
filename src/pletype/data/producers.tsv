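family	lp_name	species	strain_id	status	validation_strain	additional_strain	accession
Factin	Cichofactin	P. cichorii	SF1-54	known	false	false
Factin	Cichofactin	P. cichorii	JBC1	known	false	false
Factin	Syringafactin	P. syringae pv. tomato	DC3000	known	false	false
Factin	Virginiafactin	Pseudomonas sp.	QS1027	known	false	false
Bananamide	MDN-0066	P. granadensis	LMG 27940	known	true	false
Bananamide	Bananamide I-III (A-C)	P. bananamidigenes	BW11P2	known	true	false
Bananamide	Bananamide D-G	P. botevensis	COW3	known	true	false
Viscosin	Viscosin	P. fluorescens	BBc6R8	known	false	false
Viscosin	Viscosin	P. fluorescens	SBW25	known	false	false
Viscosin	Viscosinamide	P. carnis	DR54	known	false	false
Viscosin	Viscosinamide	Pseudomonas sp.	A2W4.9	known	false	false
Viscosin	Viscosinamide	Pseudomonas sp.	U2W1.5	known	false	false
Viscosin	WLIP	P. chlororaphis subsp. aurantiaca	PB-St2	known	false	false
Viscosin	WLIP	P. wayambapalatensis	RW10S2	known	false	false
Viscosin	WLIP	Pseudomonas sp.	NSE1	known	false	false
Viscosin	WLIP	P. fluorescens	LMG 5329	known	false	false
Viscosin	Massetolide	P. lactis	SS101	known	false	false
Viscosin	Pseudodesmin	Pseudomonas sp.	COR52	known	false	false
Viscosin	Pseudodesmin	P. tolaasii	NCPPB 2192 = LMG 2342	known	false	false
Viscosin	Pseudophomin	Pseudomonas sp.	BRG-100	known	false	false
Orfamide	Orfamide	P. protegens	Pf-5	known	false	false
Orfamide	Orfamide	P. protegens	CHA0	known	false	false
Orfamide	Orfamide	P. aestus	CMR5c	known	false	false
Orfamide	Orfamide	P. sessilinigenes	CMR12a	known	false	false
Poaeamide	Poaeamide A	P. poae	RE*1-1-14	known	false	false
Poaeamide	Poaeamide B	P. synxantha	CR32	known	false	false
Poaeamide	PPZPM	Pseudomonas sp.	Wu6	known	false	false
Amphisin	Amphisin	P. fluorescens	DSS73	known	true	false
Amphisin	Anikasin	P. fluorescens	HKI0770	known	false	false
Amphisin	Arthrofactin	Pseudomonas sp.	MIS38	known	true	false
Amphisin	Lokisin	Pseudomonas sp.	DSS41	known	false	false
Amphisin	Lokisin	Pseudomonas sp.	COR10	known	true	true
Amphisin	Milkisin	P. crudilactis	UCMA 17988	known	true	false
Amphisin	Tensin-stechlisin	Pseudomonas sp.	FhG100052	known	false	false
Gacamide	Gacamide	P. fluorescens	Pf0-1	known	true	false
Gacamide	Cocoyamide	Pseudomonas sp.	COW5	known	true	false
Putisolvin	Putisolvin I-II	P. putida	PCL1445	known	false	false
Putisolvin	Putisolvin I-II	P. capeferrum	WCS358	known	true	false
Putisolvin	Putisolvin III-V	Pseudomonas sp.	COR19	known	true	false
Putisolvin	Putisolvin III-V	P. vlassakiae	WCU_60	known	true	false
Putisolvin	Putisolvin III-V	P. vlassakiae	WCU_64	known	true	false
Xantholysin	Xantholysin	P. mosselii	BW11M1	known	true	false
Xantholysin	Xantholysin	P. soli	LMG 27941	known	true	false
Xantholysin	Xantholysin	Pseudomonas sp.	250J	known	false	false
Entolysin	Entolysin	P. entomophila	L48	known	true	false
Tolaasin	Tolaasin I	P. tolaasii	NCPPB 2192 = LMG 2342	known	true	false
Tolaasin	Tolaasin F	P. costantinii	DSM 16734 = LMG 22119	known	true	false
Tolaasin	Sessilin	P. sessilinigenes	CMR12a	known	true	false
Peptin	Syringopeptin SP22	P. syringae pv. syringae	B301D	known	false	false
Peptin	Syringopeptin SP25	P. syringae pv. atrofaciens	NCPPB 2612 = LMG 5095	known	false	false
Peptin	Cichopeptin	P. cichorii	SF1-54	known	false	false
Peptin	Fuscopeptin	P. fuscovaginae	LMG 2158	known	false	false
Peptin	Jessenipeptin	Pseudomonas sp.	QS1027	known	false	false
Peptin	Nunapeptin	P. fluorescens	In5	known	false	false
Peptin	Corpeptin	P. corrugata	NCPPB 2445 = LMG 2172	known	false	false
Peptin	Thanapeptin	Pseudomonas sp.	SH-C52	known	false	false
Peptin	Sclerosin	P. brassicacearum	DF41	known	false	false
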