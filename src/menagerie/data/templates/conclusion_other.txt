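The overall significance of these observations remains unclear.
Further experiments are needed to clarify these findings.
These data describe the system without settling its translational relevance.
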