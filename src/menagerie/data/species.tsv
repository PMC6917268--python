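surface	canonical	ids	semtypes	category
human	Human	UMLS:C0086418	Human	species_signal
humans	Human	UMLS:C0086418	Human	species_signal
patient	Human	UMLS:C0030705	Human	species_signal
patients	Human	UMLS:C0030705	Human	species_signal
clinical trial	Human	UMLS:C0008976	Human	species_signal
clinical trials	Human	UMLS:C0008976	Human	species_signal
men	Human	UMLS:C0086418	Human	species_signal
women	Human	UMLS:C0086418	Human	species_signal
volunteers	Human	UMLS:C0086418	Human	species_signal
mouse	Mouse	UMLS:C0026809	Mammal	species_signal
mice	Mouse	UMLS:C0026809	Mammal	species_signal
murine	Mouse	UMLS:C0026809	Mammal	species_signal
rat	Rat	UMLS:C0034693	Mammal	species_signal
rats	Rat	UMLS:C0034693	Mammal	species_signal
rodent	Rodent	UMLS:C0035804	Mammal	species_signal
rodents	Rodent	UMLS:C0035804	Mammal	species_signal
primate	Non-human primate	UMLS:C0033147	Mammal	species_signal
primates	Non-human primate	UMLS:C0033147	Mammal	species_signal
non-human primate	Non-human primate	UMLS:C0033147	Mammal	species_signal
non-human primates	Non-human primate	UMLS:C0033147	Mammal	species_signal
nonhuman primate	Non-human primate	UMLS:C0033147	Mammal	species_signal
nonhuman primates	Non-human primate	UMLS:C0033147	Mammal	species_signal
macaque	Macaque	UMLS:C0024462	Mammal	species_signal
macaques	Macaque	UMLS:C0024462	Mammal	species_signal
macaca	Macaque	UMLS:C0024462	Mammal	species_signal
rhesus monkey	Macaque	UMLS:C0024462	Mammal	species_signal
rhesus monkeys	Macaque	UMLS:C0024462	Mammal	species_signal
marmoset	Marmoset	UMLS:C0006764	Mammal	species_signal
marmosets	Marmoset	UMLS:C0006764	Mammal	species_signal
callithrix	Marmoset	UMLS:C0006764	Mammal	species_signal
vervet	Vervet monkey	UMLS:C0007817	Mammal	species_signal
vervet monkey	Vervet monkey	UMLS:C0007817	Mammal	species_signal
vervet monkeys	Vervet monkey	UMLS:C0007817	Mammal	species_signal
baboon	Baboon	UMLS:C0030442	Mammal	species_signal
baboons	Baboon	UMLS:C0030442	Mammal	species_signal
cat	Cat	UMLS:C0007450	Mammal	species_signal
cats	Cat	UMLS:C0007450	Mammal	species_signal
feline	Cat	UMLS:C0007450	Mammal	species_signal
dog	Dog	UMLS:C0012984	Mammal	species_signal
dogs	Dog	UMLS:C0012984	Mammal	species_signal
canine	Dog	UMLS:C0012984	Mammal	species_signal
rabbit	Rabbit	UMLS:C0034721	Mammal	species_signal
rabbits	Rabbit	UMLS:C0034721	Mammal	species_signal
frog	Frog	UMLS:C0003063	Amphibian	species_signal
frogs	Frog	UMLS:C0003063	Amphibian	species_signal
xenopus	Frog	UMLS:C0043425	Amphibian	species_signal
zebrafish	Zebrafish	UMLS:C0206663	Fish	species_signal
danio rerio	Zebrafish	UMLS:C0206663	Fish	species_signal
drosophila	Drosophila	UMLS:C0013324	Animal	species_signal
fruit fly	Drosophila	UMLS:C0013324	Animal	species_signal
fruit flies	Drosophila	UMLS:C0013324	Animal	species_signal
worm	Worm	UMLS:C0018893	Animal	species_signal
worms	Worm	UMLS:C0018893	Animal	species_signal
c. elegans	Worm	UMLS:C0007621	Animal	species_signal
caenorhabditis elegans	Worm	UMLS:C0007621	Animal	species_signal
nematode	Worm	UMLS:C0027893	Animal	species_signal
yeast	Yeast	UMLS:C0036025	Fungus	species_signal
saccharomyces cerevisiae	Yeast	UMLS:C0036025	Fungus	species_signal
animal	Animal model	UMLS:C0599779	Animal	species_signal
animals	Animal model	UMLS:C0599779	Animal	species_signal
animal model	Animal model	UMLS:C0599779	Animal	species_signal
animal models	Animal model	UMLS:C0599779	Animal	species_signal
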