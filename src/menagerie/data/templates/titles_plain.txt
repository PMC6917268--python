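A study of nigrostriatal pathology in experimental parkinsonism.
Characterization of nigral cell biology in Parkinson's disease research.
An investigation of dopaminergic signalling in experimental parkinsonism.
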