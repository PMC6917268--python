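Histological markers were quantified across experimental groups.
Biochemical assays were carried out on all samples.
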