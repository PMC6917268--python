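# Negative polarity words (BAD). Disorder-group mentions also count as BAD.
exacerbate
worsen
deficit
impairment
degeneration
toxicity
death
loss
dysfunction
deterioration
adverse
harmful
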