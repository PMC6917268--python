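# Surfaces claimed by the model or intervention modules.
dopa
l-dopa
levodopa
mptp
mptp(+)
6-ohda
liraglutide
rotenone
paraquat
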