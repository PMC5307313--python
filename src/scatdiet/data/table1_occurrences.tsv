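taxon	common_name	rank	genus	family	order	class_name	lpc	agc
Niviventer confucianus	Chinese white-bellied rat	species	Niviventer	Muridae	Rodentia	Mammalia	58	2
Apodemus draco	South China field mouse	species	Apodemus	Muridae	Rodentia	Mammalia	41	0
Eothenomys chinensis	Sichuan Chinese vole	species	Eothenomys	Cricetidae	Rodentia	Mammalia	35	1
Niviventer excelsior	Large white-bellied rat	species	Niviventer	Muridae	Rodentia	Mammalia	25	1
Eothenomys melanogaster	Pere David's vole	species	Eothenomys	Cricetidae	Rodentia	Mammalia	18	0
Apodemus chevrieri	Chevrier's field mouse	species	Apodemus	Muridae	Rodentia	Mammalia	5	0
Leopoldamys edwardsi	Edwards's long-tailed giant rat	species	Leopoldamys	Muridae	Rodentia	Mammalia	5	0
Trogopterus xanthipes	Complex-toothed flying squirrel	species	Trogopterus	Sciuridae	Rodentia	Mammalia	2	1
Rhizomys sinensis	Chinese bamboo rat	species	Rhizomys	Spalacidae	Rodentia	Mammalia	1	4
Sciurotamias davidianus	Chinese rock squirrel	species	Sciurotamias	Sciuridae	Rodentia	Mammalia	1	1
Apodemus peninsulae	Korean field mouse	species	Apodemus	Muridae	Rodentia	Mammalia	1	0
Hystrix brachyura	Malayan porcupine	species	Hystrix	Hystricidae	Rodentia	Mammalia	1	0
Dremomys pernyi	Perny's long-nosed squirrel	species	Dremomys	Sciuridae	Rodentia	Mammalia	0	1
Ochotona spp.	Pikas	genus	Ochotona	Ochotonidae	Lagomorpha	Mammalia	71	3
Carnivora	Undetermined carnivore	order			Carnivora	Mammalia	27	2
Felidae	Undetermined felid	family		Felidae	Carnivora	Mammalia	1	0
Tragopan temminckii	Temminck's tragopan	species	Tragopan	Phasianidae	Galliformes	Aves	15	6
Gallus gallus	Red jungle fowl	species	Gallus	Phasianidae	Galliformes	Aves	7	2
Chrysolophus pictus	Golden pheasant	species	Chrysolophus	Phasianidae	Galliformes	Aves	3	0
Bambusicola thoracicus	Chinese bamboo partridge	species	Bambusicola	Phasianidae	Galliformes	Aves	1	0
Passeriformes	Undetermined passerine	order			Passeriformes	Aves	8	1
Timaliidae	Old World babblers	family		Timaliidae	Passeriformes	Aves	4	0
Prinia inornata	Plain prinia	species	Prinia	Cisticolidae	Passeriformes	Aves	4	1
Turdidae	Thrushes	family		Turdidae	Passeriformes	Aves	2	1
Alcippe chrysotis	Golden-breasted fulvetta	species	Alcippe	Timaliidae	Passeriformes	Aves	2	0
Yuhina spp.	Yuhinas	genus	Yuhina	Zosteropidae	Passeriformes	Aves	2	0
Episoriculus macrurus	Long-tailed mountain shrew	species	Episoriculus	Soricidae	Soricomorpha	Mammalia	7	1
Sorex spp.	Shrews	genus	Sorex	Soricidae	Soricomorpha	Mammalia	7	0
Scaptonyx fusicaudus	Long-tailed mole	species	Scaptonyx	Talpidae	Soricomorpha	Mammalia	3	0
Uropsilus soricipes	Chinese shrew mole	species	Uropsilus	Talpidae	Soricomorpha	Mammalia	3	0
Soricinae	Red-toothed shrews	subfamily		Soricidae	Soricomorpha	Mammalia	1	0
Sus scrofa	Wild boar	species	Sus	Suidae	Artiodactyla	Mammalia	9	2
Budorcas taxicolor	Takin	species	Budorcas	Bovidae	Artiodactyla	Mammalia	3	2
Naemorhedus griseus	Chinese goral	species	Naemorhedus	Bovidae	Artiodactyla	Mammalia	2	0
Moschus berezovskii	Forest musk deer	species	Moschus	Moschidae	Artiodactyla	Mammalia	0	1
Rhinopithecus roxellana	Golden snub-nosed monkey	species	Rhinopithecus	Cercopithecidae	Primates	Mammalia	2	1
Macaca mulatta	Rhesus macaque	species	Macaca	Cercopithecidae	Primates	Mammalia	0	1
Anas spp.	Ducks	genus	Anas	Anatidae	Anseriformes	Aves	2	0
Plestiodon capito	Yellow-striped skink	species	Plestiodon	Scincidae	Lacertiformes	Reptilia	1	0
Cyprinidae	Carps	family		Cyprinidae	Cypriniformes	Actinopterygii	1	0
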