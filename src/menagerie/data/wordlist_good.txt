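# Positive polarity words (GOOD).
ameliorate
improve
improved
improvement
protect
protective
protection
neuroprotective
neuroprotection
recover
recovered
recovery
restore
restoration
restorative
rescue
benefit
beneficial
efficacy
efficacious
effective
therapeutic
promising
safe
safety
tolerable
tolerated
viability
viable
survival
functional
healthy
normal
normalize
preserve
preservation
repair
regenerate
regeneration
remission
relief
relieve
success
successful
favorable
positive
potent
heal
healing
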