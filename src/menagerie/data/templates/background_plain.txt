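Nigrostriatal degeneration underlies the cardinal features of Parkinson's disease.
The molecular basis of progressive nigral cell death is incompletely understood.
Dopaminergic signalling in the basal ganglia has been studied extensively.
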