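# Five independent variables for the 22 study species (printed trait table).
# Strategy: 0 web builder, 1 non-web. Specific: 1 sit&wait .. 5.5 tangle web.
# Silk: 1 none/MAP dragline .. 4 viscous. Type: 1 standard-7 .. 4 standard-7
# + cribellum + paracribellar + pseudoflagelliform. Instar: maximum number of
# instars to the adult female.
species	family	Strategy	Specific	Silk	Type	Instar
Tibellus_oblongus	Philodromidae	1	2	1	1	6
Xysticus_cristatus	Thomisidae	1	1.5	1	1	6
Xerolycosa_nemoralis	Lycosidae	1	3	1	1	10
Pardosa_lugubris	Lycosidae	1	3	1	1	7
Pardosa_amentata	Lycosidae	1	3	1	1	9
Hogna_carolinensis	Lycosidae	1	2	1	2	12
Arctosa_lutetiana	Lycosidae	1	1.5	1.5	1	9
Arctosa_alpigena_lamperti	Lycosidae	1	3	1	1	10
Dolomedes_tenebrosus	Pisauridae	1	1	1	2	13
Tengella_perfuga	Zoropsidae	0	4.5	3	2.5	12
Argyroneta_aquatica	Dictynidae	0	4	2	1	6
Eratigena_atrica	Agelenidae	0	4.5	2	1	9
Phyxelida_tanganensis	Phyxelididae	0	4	3	4	8
Hyptiotes_paradoxus	Uloboridae	0	5	3	4	6
Metellina_segmentata	Tetragnathidae	0	5	4	3	5
Mimetus_puritanus	Mimetidae	1	2.5	1	1.5	7
Mimetus_notius	Mimetidae	1	2.5	1	1.5	7
Neoscona_theisi	Araneidae	0	5	4	3	7
Araneus_cavaticus	Araneidae	0	5	4	3	12
Araneus_diadematus	Araneidae	0	5	4	3	10
Larinioides_cornutus	Araneidae	0	5	4	3	7
Enoplognatha_ovata	Theridiidae	0	5.5	4	3	4
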