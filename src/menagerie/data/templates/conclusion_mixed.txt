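The intervention produced marked improvement but also increased toxicity.
Treatment restored dopaminergic function yet worsened other adverse effects.
The approach alleviated motor deficits although it exacerbated cell death.
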