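family	lp_name	species	strain_id	fatty_acid	residues	macrocycle	inherited
Bananamide	MDN-0066	P. granadensis	LMG 27940	3-OH C10:0	Leu-Glu-Thr-Leu-Leu-Ser-Leu-Ile	3-8
Bananamide	Bananamide I (A)	P. bananamidigenes	BW11P2	3-OH C12:0	Leu-Asp-Thr-Leu-Leu-Gln-Leu-Ile	3-8
Bananamide	Bananamide II (B)	P. bananamidigenes	BW11P2	3-OH C10:0	Leu-Asp-Thr-Leu-Leu-Gln-Leu-Ile	3-8	species,strain_id
Bananamide	Bananamide III (C)	P. bananamidigenes	BW11P2	3-OH C12:1	Leu-Asp-Thr-Leu-Leu-Gln-Leu-Ile	3-8	species,strain_id
Bananamide	Bananamide D	P. botevensis	COW3	3-OH C12:1	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Ile	3-8
Bananamide	Bananamide E	P. botevensis	COW3	3-OH C12:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Ile	3-8	species,strain_id
Bananamide	Bananamide F	P. botevensis	COW3	3-OH C10:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Ile	3-8	species,strain_id
Bananamide	Bananamide G	P. botevensis	COW3	3-OH C12:1	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Val	3-8	species,strain_id
Bananamide	Prosekin	P. prosekii	LMG 26867	3-OH C10:0	Leu-Glu-Thr-Leu-Leu-Ser-Ile-Ile	3-8
Amphisin	Amphisin	P. fluorescens	DSS73	3-OH C10:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Gln-Leu-Ile-Asp	3-11
Amphisin	Anikasin	P. fluorescens	HKI0770	3-OH C10:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Ser-Leu-Ile-Asp	3-11
Amphisin	Arthrofactin	Pseudomonas sp.	MIS38	3-OH C10:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Ser-Ile-Ile-Asp	3-11
Amphisin	Milkisin	P. crudilactis	UCMA 17988	3-OH C10:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Gln-Leu-Ile-Glu	3-11
Amphisin	Stechlisin B2	Pseudomonas sp.	FhG100052	3-OH C8:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Gln-Leu-Ile-Glu	3-11
Amphisin	Stechlisin C3	Pseudomonas sp.	FhG100052	3-OH C10:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Gln-Leu-Val-Glu	3-11	species,strain_id
Amphisin	Stechlisin D3	Pseudomonas sp.	FhG100052	3-OH C10:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Gln-Leu-Leu-Glu	3-11	species,strain_id
Amphisin	Stechlisin E2	Pseudomonas sp.	FhG100052	3-OH C10:0	Leu-Glu-Thr-Leu-Leu-Ser-Leu-Gln-Leu-Ile-Glu	3-11	species,strain_id
Amphisin	Stechlisin F	Pseudomonas sp.	FhG100052	3-OH C12:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Gln-Leu-Ile-Glu	3-11	species,strain_id
Amphisin	Tensin	Pseudomonas sp.	FhG100052	3-OH C10:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Gln-Leu-Ile-Glu	3-11
Amphisin	Tensin	P. zeae	OE 48.2	3-OH C10:0	Leu-Asp-Thr-Leu-Leu-Ser-Leu-Gln-Leu-Ile-Glu	3-11	fatty_acid,residues
Putisolvin	Putisolvin I	P. putida	PCL1445	C6:0	Leu-Glu-Leu-Ile-Gln-Ser-Val-Ile-Ser-Leu-Val-Ser	9-12
Putisolvin	Putisolvin II	P. putida	PCL1445	C6:0	Leu-Glu-Leu-Ile-Gln-Ser-Val-Ile-Ser-Leu-Ile-Ser	9-12	species,strain_id
Putisolvin	Putisolvin III	Pseudomonas sp.	COR19	C6:0	Leu-Glu-Leu-Leu-Gln-Ser-Val-Leu-Ser-Leu-Val-Ser	9-12
Putisolvin	Putisolvin IV	P. vlassakiae	WCU_64	C6:0	Leu-Glu-Leu-Leu-Gln-Ser-Val-Leu-Ser-Leu-Ile-Ser	9-12
Putisolvin	Putisolvin V	P. fulva	LMG 11722	C6:0	Leu-Glu-Leu-Leu-Gln-Ser-Val-Leu-Ser-Leu-Leu-Ser	9-12
Xantholysin	Xantholysin A	P. mosselii	BW11M1	3-OH C10:0	Leu-Glu-Gln-Val-Leu-Gln-Ser-Val-Leu-Gln-Leu-Leu-Gln-Ile	7-14
Xantholysin	Xantholysin A	P. soli	LMG 27941	3-OH C10:0	Leu-Glu-Gln-Val-Leu-Gln-Ser-Val-Leu-Gln-Leu-Leu-Gln-Ile	7-14	fatty_acid,residues
Xantholysin	Xantholysin A	Pseudomonas sp.	250J	3-OH C10:0	Leu-Glu-Gln-Val-Leu-Gln-Ser-Val-Leu-Gln-Leu-Leu-Gln-Ile	7-14	fatty_acid,residues
Xantholysin	Xantholysin A	P. xantholysinigenes	RW9S1A	3-OH C10:0	Leu-Glu-Gln-Val-Leu-Gln-Ser-Val-Leu-Gln-Leu-Leu-Gln-Ile	7-14	fatty_acid,residues
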