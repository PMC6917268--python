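specific	general
Macaque	Non-human primate
Marmoset	Non-human primate
Vervet monkey	Non-human primate
Baboon	Non-human primate
Mouse	Rodent
Rat	Rodent
Rodent	Animal model
Non-human primate	Animal model
Cat	Animal model
Dog	Animal model
Rabbit	Animal model
Frog	Animal model
Zebrafish	Animal model
Drosophila	Animal model
Worm	Animal model
Yeast	Animal model
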