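Weekly testing included {functional} in all groups.
Assessment of {functional} was performed throughout the study.
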