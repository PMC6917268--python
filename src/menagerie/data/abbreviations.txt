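# Sentence-splitter guard list: a period after these tokens never ends a sentence.
e.g
i.e
i.p
i.v
s.c
p.o
fig
figs
vs
cf
al
approx
ca
wk
hr
min
sec
dr
st
resp
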