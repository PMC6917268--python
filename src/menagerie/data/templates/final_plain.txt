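Future studies will extend these observations to additional systems.
These data inform the design of subsequent experiments.
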