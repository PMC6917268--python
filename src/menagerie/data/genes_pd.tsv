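surface	canonical	ids	semtypes	category
parkin	PRKN	NCBIGene:5071	Gene or Genome	gene
prkn	PRKN	NCBIGene:5071	Gene or Genome	gene
park2	PRKN	NCBIGene:5071	Gene or Genome	gene
alcohol dehydrogenase 3	ADH1C	NCBIGene:126	Enzyme	gene
adh1c	ADH1C	NCBIGene:126	Gene or Genome	gene
alpha-synuclein	SNCA	NCBIGene:6622	Amino Acid, Peptide, or Protein	gene
snca	SNCA	NCBIGene:6622	Gene or Genome	gene
synuclein alpha	SNCA	NCBIGene:6622	Gene or Genome	gene
lrrk2	LRRK2	NCBIGene:120892	Gene or Genome	gene
dardarin	LRRK2	NCBIGene:120892	Amino Acid, Peptide, or Protein	gene
pink1	PINK1	NCBIGene:65018	Gene or Genome	gene
dj-1	PARK7	NCBIGene:11315	Gene or Genome	gene
park7	PARK7	NCBIGene:11315	Gene or Genome	gene
gba	GBA	NCBIGene:2629	Gene or Genome	gene
glucocerebrosidase	GBA	NCBIGene:2629	Enzyme	gene
mapt	MAPT	NCBIGene:4137	Gene or Genome	gene
tau protein	MAPT	NCBIGene:4137	Amino Acid, Peptide, or Protein	gene
uchl1	UCHL1	NCBIGene:7345	Gene or Genome	gene
dopaminergic d1 receptor	DRD1	NCBIGene:24316	Amino Acid, Peptide, or Protein	gene
d1 receptor	DRD1	NCBIGene:24316	Amino Acid, Peptide, or Protein	gene
drd1	DRD1	NCBIGene:24316	Gene or Genome	gene
dopamine transporter	SLC6A3	NCBIGene:6531	Amino Acid, Peptide, or Protein	gene
slc6a3	SLC6A3	NCBIGene:6531	Gene or Genome	gene
tyrosine hydroxylase	TH	NCBIGene:7054	Enzyme	gene
vps35	VPS35	NCBIGene:55737	Gene or Genome	gene
atp13a2	ATP13A2	NCBIGene:23400	Gene or Genome	gene
gdnf	GDNF	NCBIGene:2668	Amino Acid, Peptide, or Protein	gene
dopamine receptors	Dopamine receptor	UMLS:C0012964	Amino Acid, Peptide, or Protein	gene
d2 receptors	Dopamine D2 receptor	UMLS:C0012963	Amino Acid, Peptide, or Protein	gene
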