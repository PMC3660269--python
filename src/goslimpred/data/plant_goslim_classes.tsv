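namespace	class_name	acronym	incomplete	n_proteins
molecular_function	Nucleotide binding	Ntbind	0	47
molecular_function	Molecular function	MF*	1	268
molecular_function	DNA binding	DnaBind	0	107
molecular_function	Transcription factor activity	TranscFact	0	307
molecular_function	RNA binding	RnaBind	0	43
molecular_function	Catalytic activity	Catal*	1	334
molecular_function	Receptor binding	RecBind	0	38
molecular_function	Transporter activity	Transp	0	125
molecular_function	Binding	Bind*	1	173
molecular_function	Protein binding	ProtBind*	1	630
molecular_function	Kinase activity	Kinase	0	68
molecular_function	Transferase activity	Transf*	1	173
molecular_function	Hydrolase activity	Hydrol	0	190
molecular_function	Enzyme regulator activity	EnzReg	0	41
cellular_component	Cellular component	CC*	1	234
cellular_component	Extracellular region	ExtcellReg	0	109
cellular_component	Cell wall	CellWall	0	77
cellular_component	Intracellular	Intracell*	1	167
cellular_component	Nucleus	Nucleus*	1	421
cellular_component	Nucleoplasm	NuclPlasm	0	51
cellular_component	Nucleolus	Nucleolus	0	84
cellular_component	Cytoplasm	CitPlasm*	1	168
cellular_component	Mitochondrion	Mitochond	0	244
cellular_component	Endosome	Endosome	0	58
cellular_component	Vacuole	Vacuole	0	171
cellular_component	Peroxisome	Peroxisome	0	32
cellular_component	Endoplasmatic reticulum	EndRet	0	109
cellular_component	Golgi apparatus	GolgiApp	0	100
cellular_component	Cytosol	Cytosol	0	389
cellular_component	Ribosome	Ribosome	0	98
cellular_component	Plasma membrane	PlasmMb	0	353
cellular_component	Plastid	Plastid	0	696
cellular_component	Thylakoid	Thylk	0	147
cellular_component	Membrane	Mb*	1	472
biological_process	Reproduction	Reprod*	1	337
biological_process	Carbohydrate metabolic process	ChMet	0	315
biological_process	Generation of precursor metabolites and energy	MetEn	0	150
biological_process	Nucleobase, nucleoside, nucleotide, nucleic acid metabolic process	NaMet*	1	712
biological_process	DNA metabolic process	DnaMet	0	191
biological_process	Translation	Transl	0	82
biological_process	Protein modification process	ProtMod	0	391
biological_process	Lipid metabolic process	LipMet	0	324
biological_process	Transport	Transport	0	531
biological_process	Response to stress	StressResp	0	790
biological_process	Cell cycle	CellCycle	0	234
biological_process	Cell communication	CellComm*	1	66
biological_process	Signal transduction	SigTransd	0	305
biological_process	Cell-cell signaling	Cell-cell	0	53
biological_process	Multicellular organismal development	MultDev*	1	490
biological_process	Biological process	BP*	1	879
biological_process	Metabolic process	Met*	1	279
biological_process	Cell death	CellDeath	0	95
biological_process	Catabolic process	Catabolic	0	479
biological_process	Biosynthetic process	Biosint*	1	1125
biological_process	Response to external stimulus	ExtResp*	1	65
biological_process	Tropism	Tropism	0	36
biological_process	Response to biotic stimulus	BioResp	0	275
biological_process	Response to abiotic stimulus	AbioResp	0	642
biological_process	Anatomical structure morphogenesis	StrMorph	0	366
biological_process	Response to endogenous stimulus	EndoResp	0	332
biological_process	Embryonic development	EmbDev	0	139
biological_process	Post-embryonic development	PostDev*	1	375
biological_process	Pollination	Poll	0	43
biological_process	Flower development	FlowerDev	0	228
biological_process	Cellular process	CP*	1	1486
biological_process	Response to extracellular stimulus	ExtcellResp	0	59
biological_process	Photosyntesis	Photosyn	0	102
biological_process	Cellular component organization	CellOrg	0	757
biological_process	Cell growth	CellGrowth	0	133
biological_process	Protein metabolic process	ProtMet*	1	187
biological_process	Cellular homeostasis	CellHom	0	53
biological_process	Secondary metabolic process	SecMet	0	164
biological_process	Cell differentiation	CellDiff	0	267
biological_process	Growth	Growth*	1	64
biological_process	Regulation of gene expression, epigenetic	RGE	0	103
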