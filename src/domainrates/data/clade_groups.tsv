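# Default vertebrate clade-group table: 26 groups (taxonomic classes to
# infraorders), one or more representative taxa per group.  Edit or replace
# for real analyses; taxon ids must match the alignment labels.
taxon_id	group_id	group_name	superorder
sea_lamprey	1	Cyclostomata	Agnatha
white_shark	2	Chondrichthyes	Gnathostomata
gray_bichir	3	Cladistia	Actinopterygii
sterlet_sturgeon	4	Chondrostei	Actinopterygii
spotted_gar	5	Holostei	Actinopterygii
zebrafish	6	Teleostei	Actinopterygii
medaka	6	Teleostei	Actinopterygii
takifugu	6	Teleostei	Actinopterygii
coelacanth	7	Coelacanthi_Dipnoi	Sarcopterygii
west_african_lungfish	7	Coelacanthi_Dipnoi	Sarcopterygii
xenopus_laevis	8	Amphibia	Tetrapoda
xenopus_tropicalis	8	Amphibia	Tetrapoda
tiger_salamander	8	Amphibia	Tetrapoda
green_anole	9	Reptilia	Sauropsida
western_rattlesnake	9	Reptilia	Sauropsida
painted_turtle	9	Reptilia	Sauropsida
ostrich	10	Palaeognathae	Aves
chicken	11	Neognathae	Aves
zebra_finch	11	Neognathae	Aves
platypus	12	Monotremata	Mammalia
gray_short_tailed_opossum	13	Marsupialia	Mammalia
florida_manatee	14	Sirenia	Afrotheria
dugong	14	Sirenia	Afrotheria
african_elephant	15	Proboscidea	Afrotheria
asian_elephant	15	Proboscidea	Afrotheria
aardvark	16	Afroinsectiphilia	Afrotheria
cape_elephant_shrew	16	Afroinsectiphilia	Afrotheria
cape_golden_mole	16	Afroinsectiphilia	Afrotheria
minke_whale	17	Cetacea	Laurasiatheria
bottlenose_dolphin	17	Cetacea	Laurasiatheria
sperm_whale	17	Cetacea	Laurasiatheria
orca	17	Cetacea	Laurasiatheria
hippopotamus	18	Hippopotamidae	Laurasiatheria
cattle	19	Ruminantia	Laurasiatheria
sheep	19	Ruminantia	Laurasiatheria
goat	19	Ruminantia	Laurasiatheria
pig	20	Suina	Laurasiatheria
weddell_seal	21	Pinnipedia	Laurasiatheria
harbor_seal	21	Pinnipedia	Laurasiatheria
california_sea_lion	21	Pinnipedia	Laurasiatheria
walrus	21	Pinnipedia	Laurasiatheria
american_mink	22	Musteloidea	Laurasiatheria
sea_otter	22	Musteloidea	Laurasiatheria
domestic_ferret	22	Musteloidea	Laurasiatheria
polar_bear	23	Ursidae	Laurasiatheria
brown_bear	23	Ursidae	Laurasiatheria
american_black_bear	23	Ursidae	Laurasiatheria
giant_panda	23	Ursidae	Laurasiatheria
european_rabbit	24	Lagomorpha	Euarchontoglires
american_pika	24	Lagomorpha	Euarchontoglires
house_mouse	25	Rodentia	Euarchontoglires
norway_rat	25	Rodentia	Euarchontoglires
guinea_pig	25	Rodentia	Euarchontoglires
thirteen_lined_ground_squirrel	25	Rodentia	Euarchontoglires
american_beaver	25	Rodentia	Euarchontoglires
naked_mole_rat	25	Rodentia	Euarchontoglires
human	26	Primates	Euarchontoglires
chimpanzee	26	Primates	Euarchontoglires
rhesus_macaque	26	Primates	Euarchontoglires
sunda_flying_lemur	26	Primates	Euarchontoglires
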