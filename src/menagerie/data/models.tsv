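surface	canonical	ids	semtypes	category
1-methyl-4-phenyl-1,2,3,6-tetrahydropyridine	MPTP	MeSH:D015632	Hazardous or Poisonous Substance	model_signal
mptp	MPTP	MeSH:D015632	Hazardous or Poisonous Substance	model_signal
6-hydroxydopamine	6-OHDA	MeSH:D016627	Hazardous or Poisonous Substance	model_signal
6-ohda	6-OHDA	MeSH:D016627	Hazardous or Poisonous Substance	model_signal
1-methyl-4-phenylpyridinium	MPP	MeSH:D015655	Hazardous or Poisonous Substance	model_signal
mpp	MPP	MeSH:D015655	Hazardous or Poisonous Substance	model_signal
mptp/probenecid	MPTPp	MeSH:D015632	Hazardous or Poisonous Substance	model_signal
mptpp	MPTPp	MeSH:D015632	Hazardous or Poisonous Substance	model_signal
hemiparkinsonian	Hemi-parkinsonian	UMLS:C0030569	Experimental Model of Disease	model_signal
hemi-parkinsonian	Hemi-parkinsonian	UMLS:C0030569	Experimental Model of Disease	model_signal
hemiparkinsonism	Hemi-parkinsonian	UMLS:C0030569	Experimental Model of Disease	model_signal
levodopa-induced dyskinesia	Levodopa-induced dyskinesia	UMLS:C1970038	Experimental Model of Disease	model_signal
l-dopa-induced dyskinesia	Levodopa-induced dyskinesia	UMLS:C1970038	Experimental Model of Disease	model_signal
lid	Levodopa-induced dyskinesia	UMLS:C1970038	Experimental Model of Disease	model_signal
rotenone	Rotenone	MeSH:D012402	Hazardous or Poisonous Substance	model_signal
paraquat	Paraquat	MeSH:D010269	Hazardous or Poisonous Substance	model_signal
lactacystin	Lactacystin	MeSH:C060350	Hazardous or Poisonous Substance	model_signal
maneb	Maneb	MeSH:D008344	Hazardous or Poisonous Substance	model_signal
reserpine	Reserpine	MeSH:D012110	Pharmacologic Substance	model_signal
haloperidol	Haloperidol	MeSH:D006220	Pharmacologic Substance	model_signal
galantamine	Galantamine	MeSH:D005702	Pharmacologic Substance	model_signal
lipopolysaccharide	Lipopolysaccharide induced model	MeSH:D008070	Hazardous or Poisonous Substance	model_signal
lipopolysaccharides	Lipopolysaccharide induced model	MeSH:D008070	Hazardous or Poisonous Substance	model_signal
lps	Lipopolysaccharide induced model	MeSH:D008070	Hazardous or Poisonous Substance	model_signal
tremulous jaw movement	Tremulous jaw movement model	UMLS:C0751608	Experimental Model of Disease	model_signal
1bntiq	1BnTIQ	MeSH:C093208	Hazardous or Poisonous Substance	model_signal
transgenic	Genetically altered model	UMLS:C0598632	Experimental Model of Disease	model_signal
knockout	Genetically altered model	UMLS:C0599779	Experimental Model of Disease	model_signal
knock-out	Genetically altered model	UMLS:C0599779	Experimental Model of Disease	model_signal
knockin	Genetically altered model	UMLS:C1518418	Experimental Model of Disease	model_signal
knock-in	Genetically altered model	UMLS:C1518418	Experimental Model of Disease	model_signal
mutant	Genetically altered model	UMLS:C0026882	Experimental Model of Disease	model_signal
mutation carriers	Genetically altered model	UMLS:C0026882	Experimental Model of Disease	model_signal
overexpressing	Genetically altered model	UMLS:C1514559	Experimental Model of Disease	model_signal
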