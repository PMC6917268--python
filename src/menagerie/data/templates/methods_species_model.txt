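Adult {species} were given {model} and nigral tissue was examined.
We administered {model} to {species} over a two-week period.
Groups of {species} were exposed to {model} under standard conditions.
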