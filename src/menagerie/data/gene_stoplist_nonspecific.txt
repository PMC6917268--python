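# Non-specific genetic terms.
transcription factor
transcription factors
protein
proteins
candidate gene
candidate genes
enzyme
enzymes
kinase
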