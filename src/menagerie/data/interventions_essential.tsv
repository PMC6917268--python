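surface	canonical	ids	semtypes	category
levodopa	levodopa	MeSH:D007980	Pharmacologic Substance|Organic Chemical	chemical
l-dopa	levodopa	MeSH:D007980	Pharmacologic Substance|Organic Chemical	chemical
selegiline	selegiline	MeSH:D012642	Pharmacologic Substance|Organic Chemical	chemical
deprenyl	selegiline	MeSH:D012642	Pharmacologic Substance|Organic Chemical	chemical
carbidopa	carbidopa	MeSH:D002230	Pharmacologic Substance|Organic Chemical	chemical
rasagiline	rasagiline	MeSH:D000068556	Pharmacologic Substance|Organic Chemical	chemical
pramipexole	pramipexole	MeSH:D000068587	Pharmacologic Substance|Organic Chemical	chemical
ropinirole	ropinirole	MeSH:D000077302	Pharmacologic Substance|Organic Chemical	chemical
rotigotine	rotigotine	MeSH:D000068596	Pharmacologic Substance|Organic Chemical	chemical
amantadine	amantadine	MeSH:D000547	Pharmacologic Substance|Organic Chemical	chemical
apomorphine	apomorphine	MeSH:D001058	Pharmacologic Substance|Organic Chemical	chemical
entacapone	entacapone	MeSH:C072257	Pharmacologic Substance|Organic Chemical	chemical
exenatide	exenatide	MeSH:D000077446	Pharmacologic Substance|Organic Chemical	chemical
coenzyme q10	coenzyme Q10	MeSH:C024989	Biologically Active Substance|Organic Chemical	chemical
creatine	creatine	MeSH:D003401	Biologically Active Substance|Organic Chemical	chemical
minocycline	minocycline	MeSH:D008911	Pharmacologic Substance|Organic Chemical	chemical
rapamycin	sirolimus	MeSH:D020123	Pharmacologic Substance|Organic Chemical	chemical
sirolimus	sirolimus	MeSH:D020123	Pharmacologic Substance|Organic Chemical	chemical
caffeine	caffeine	MeSH:D002110	Pharmacologic Substance|Organic Chemical	chemical
nicotine	nicotine	MeSH:D009538	Pharmacologic Substance|Organic Chemical	chemical
melatonin	melatonin	MeSH:D008550	Hormone|Organic Chemical	chemical
curcumin	curcumin	MeSH:D003474	Pharmacologic Substance|Organic Chemical	chemical
resveratrol	resveratrol	MeSH:D000077185	Pharmacologic Substance|Organic Chemical	chemical
isradipine	isradipine	MeSH:D017275	Pharmacologic Substance|Organic Chemical	chemical
inosine	inosine	MeSH:D007288	Biologically Active Substance|Organic Chemical	chemical
deep brain stimulation	deep brain stimulation	MeSH:D046690	Therapeutic or Preventive Procedure	other
exercise	exercise	MeSH:D015444	Therapeutic or Preventive Procedure	other
physical therapy	physical therapy	MeSH:D026741	Therapeutic or Preventive Procedure	other
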