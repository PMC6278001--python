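let_name	gene	alleles	nt_change	aa_change	pfam	kog	conservation	novel
let-609	let-363	h191	C>T	R>X	Phosphatidylinositol 3- and 4-kinase	Replication, recombination and repair	I,F,M,N	0
let-643	nath-10	h500	G>A	R>K	GNAT acetyltransferase 2	General function prediction only	I,F,M,N	0
let-624/let-644/let-622	npp-6	h449,h839,h222	C>T	Q>X	Nucleoporin Nup120/160	Unknown	I,F,M,N	0
let-610	asd-2	h695	C>T	P>S	Homodimerisation region of STAR domain protein	RNA processing and modification	I,F,M,N	0
let-639/let-371	hcp-6	h779,h123	G>A	W>X	non-SMC mitotic condensation complex subunit 1	Function unknown	I,F,M,N	0
let-138/let-150/let-357	spg-7	h744,h282,h89	G>A	W>X	Peptidase family M41	Posttranslational modification, protein turnover, chaperones	I,F,M,N	0
let-163	sep-1	h483	C>T	Q>X	Peptidase family C50	Cell cycle control, cell division. Chromosome partitioning	F,M,N	0
let-133	Y71G12B.8	h440	T>A	Y>X	DEAD/DEAH box helicase	RNA processing and modification	I,F,M,N	0
let-593	inx-13	h212	C>T	Q>X	Innexin	Unknown	I,F,N	0
let-625	rpl-4	h506	G>A	D>N	Ribosomal protein L4/L1 family	RNA processing and modification	I,F,M,N	0
let-633/let-638	B0261.1	h696,h778	C>T	R>X	Myb DNA-binding like	Transcription	I,F,M,N	1
let-648	vha-16	h781	G>A	D>N	Unknown	Unknown	I,N,M,F	0
let-615	rpl-13	h529	C>T	Q>X	Ribosomal protein L13e	Translation, ribosomal structure and biogenesis	I,F,M,N	0
let-356	cdc-6	h501	G>A	G>R	ATPase family associated with various cellular activities (AAA)	Cell cycle control, cell division. Chromosome partitioning;Replication, recombination and repair	I,F,M,N	0
let-505	tufm-2	h426	C>T	R>X	Elongation factor Tu GTP binding domain	Translation, ribosomal structure and biogenesis	I,F,M,N	0
let-128	C53H9.2	h253	465+1G>A	None	50S ribosome-binding GTPase	General function prediction only	I,F,M,N	1
let-398	gpc-2	h257	C>T	Q>X	GGL domain	Signal transduction mechanisms	I,F,M,N	0
let-619/let-105	dip-2	h348,h681	C>T	H>Y	AMP-binding enzyme	General function prediction only	I,F,M,N	0
let-649/let-109	him-1	h491,h811	G>A	G>R	RecF/RecN/SMC N terminal domain	Cell cycle control, cell division. Chromosome partitioning	I,N,M,F	0
let-578	npp-11	h512	G>A	W>X	Nucleoporin FG repeat region	Intracellular trafficking, secretion, and vesicular transport;Nuclear structure	I,F,M,N	0
let-543/let-544	sacy-1	h792,h692	G>A	G>R	DEAD/DEAH box helicase	RNA processing and modification	I,F,M,N	0
let-614	rmh-1	h147	C>T	S>L	RecQ mediated genome instability protein	Function unknown	F,N	0
let-582	egg-4	h726	G>A	A>T	Protein-tyrosine phosphatase	Signal transduction mechanisms	I,F,M,N	0
let-528	cytb-5.2	h1012	G>A	W>X	Cytochrome b5-like Heme/Steroid binding domain	Energy production and conversion	I,F,M,N	0
let-511	W09C3.4	h755	262-1G>A	None	RNA polymerase Rpc34 subunit	Transcription	I,F,M,N	1
let-135	pop-1	h268	G>A	A>T	HMG (high mobility group) box	Transcription	I,F,M,N	0
let-502	spe-5	h767	C>T	S>F	ATP synthase alpha/beta family, nucleotide-binding domain	Energy production and conversion	I,F,M,N	0
let-143	npp-13	h513	G>A	G>E	Nup93/Nic96	Cell cycle control, cell division. Chromosome partitioning	I,F,M,N	0
let-571	eif-2gamma	h347	G>A	G>R	Initiation factor eIF2 gamma, C terminal	Translation, ribosomal structure and biogenesis	I,F,M,N	0
let-155	inx-21	h461	C>T	R>X	Innexin	Unknown	I,F,N	0
let-162	Y47G6A.18	h460	G>A	G>E	Golgi phosphoprotein 3 (GPP34)	Intracellular trafficking, secretion, and vesicular transport	I,F,M,N	1
let-510	Y47G6A.19	h740	1355-1G>A	None	Zinc carboxypeptidase	Function unknown	I,F,M,N	1
let-357	lpd-3	h132	1539+1G>A	None	Fragile site-associated protein C-terminus	Unknown	I,F,M,N	0
let-546	xpo-2	h227	G>A	W>X	Cse1	Intracellular trafficking, secretion, and vesicular transport;Nuclear structure	I,F,M,N	0
let-121/let-146	cdt-1	h810,h197	C>T	Q>X	DNA replication factor CDT1 like	Unknown	I,F,M,N	0
let-130	lpr-1	h773	G>A	R>Q	Unknown	Unknown	F,N	0
let-573	rpl-1	h247	C>T	T>I	Ribosomal protein L1p/L10e family	Translation, ribosomal structure and biogenesis	I,F,M,N	0
let-145	arx-1	h182	C>T	Q>X	Actin	Cytoskeleton	I,F,M,N	0
let-123/let-142/let-583	cogc-3	h413,h518,h738	G>A	G>R	Sec34-like family	Intracellular trafficking, secretion, and vesicular transport	I,F,M,N	0
let-577	sop-3	h503	G>A	E>K	Unknown	Unknown	F,M,N	0
let-548/let-144	tln-1	h356,h393	C>T	Q>X	Talin, middle domain	Cytoskeleton	I,F,M,N	0
let-131	Y71G12B.6	h817	C>T	Q>X	GDP-mannose 4,6 dehydratase	Unknown	F,N	1
let-392	nekl-2	h120,h122	G>A	G>E	Protein kinase domain	General function prediction only	F,M,N	0
let-374	lpd-5	h251	G>A	W>X	Unknown	Unknown	I,F,M,N	0
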