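# Gene surfaces that collide with common English words.
all
impact
via
set
net
map
aim
arm
act
type
large
damage
fate
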