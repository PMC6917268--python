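Cultured cells were exposed to {model} for 48 hours.
Tissue preparations were incubated with {model} before analysis.
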