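Adult {species} were studied under standard housing conditions.
Groups of {species} were randomized to the study arms.
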