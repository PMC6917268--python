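Effects of {intervention} on experimental parkinsonism.
Evaluation of {intervention} in a preclinical study of Parkinson's disease.
Assessment of {intervention} in experimental parkinsonism.
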