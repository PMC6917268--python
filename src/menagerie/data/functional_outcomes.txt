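# Functional-outcome measures: clinical scales, neurologic signs, animal assays.
unified parkinson's disease rating scale
updrs
hoehn and yahr
schwab and england
timed up and go
rotarod performance
rotarod
turning behavior
rotational behavior
apomorphine-induced rotation
open field
pole test
grip strength
beam walking
cylinder test
forelimb akinesia
gait analysis
gait
locomotor activity
motor performance
bradykinesia
akinesia
catalepsy
tremor
rigidity
postural instability
dyskinesia
freezing of gait
stride length
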