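The intervention exacerbated motor deficits and increased toxicity.
Treatment worsened nigral degeneration and caused clear adverse effects.
The approach aggravated cell death and produced harmful dysfunction.
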