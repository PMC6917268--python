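# Change words signalling an increase (MORE scope triggers).
increase
elevate
enhance
augment
raise
rise
upregulate
promote
amplify
boost
accelerate
potentiate
stimulate
induce
expand
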