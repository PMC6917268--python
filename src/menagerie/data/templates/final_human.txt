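These findings may ultimately be relevant to patients.
Whether this extends to patients remains to be established.
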