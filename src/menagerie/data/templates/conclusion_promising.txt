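The intervention alleviated motor deficits and produced marked improvement.
Treatment restored dopaminergic function and was clearly neuroprotective.
The approach reduced nigral cell loss and yielded promising functional recovery.
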