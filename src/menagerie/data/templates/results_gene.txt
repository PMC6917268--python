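Expression of {gene} was quantified in treated samples.
Levels of {gene} changed markedly following exposure.
Immunostaining for {gene} revealed altered distribution.
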