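surface	canonical	ids	semtypes	category
parkinson's disease	Parkinson disease	UMLS:C0030567	Disease or Syndrome	disorder
parkinson disease	Parkinson disease	UMLS:C0030567	Disease or Syndrome	disorder
parkinsonism	Parkinsonism	UMLS:C0242422	Disease or Syndrome	disorder
parkinsonian syndrome	Parkinsonism	UMLS:C0242422	Disease or Syndrome	disorder
neurodegeneration	Neurodegeneration	UMLS:C0524851	Disease or Syndrome	disorder
dementia	Dementia	UMLS:C0011265	Mental or Behavioral Dysfunction	disorder
alzheimer's disease	Alzheimer disease	UMLS:C0002395	Disease or Syndrome	disorder
dystonia	Dystonia	UMLS:C0013421	Sign or Symptom	disorder
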