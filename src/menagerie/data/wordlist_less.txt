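# Change words signalling a decrease (LESS scope triggers).
alleviate
decrease
reduce
attenuate
diminish
decline
lower
suppress
inhibit
downregulate
deplete
abolish
prevent
block
mitigate
weaken
lessen
drop
fall
abate
dampen
curtail
minimize
limit
restrict
slow
delay
halt
reverse
eliminate
counteract
repress
impede
shorten
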