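# Singular PLS-spigot state of each of the 27 taxa in the ancestral
# character estimation. States: Flagelliform (FL gland spigot),
# Pseudoflagelliform (PF), Modified (MS), Loss (previously possessed a
# singular spigot), None (never historically possessed one).
# source=text: assignment stated in the study's prose;
# source=figure: assignment transcribed from the figure's colour coding
# only (reconstruction; see docs/methods.md).
species	state	source
Metellina_segmentata	Flagelliform	text
Neoscona_theisi	Flagelliform	text
Araneus_cavaticus	Flagelliform	text
Araneus_diadematus	Flagelliform	text
Larinioides_cornutus	Flagelliform	text
Enoplognatha_ovata	Flagelliform	text
Mimetus_puritanus	Loss	text
Mimetus_notius	Loss	text
Tibellus_oblongus	Loss	figure
Xysticus_cristatus	Loss	figure
Xerolycosa_nemoralis	Loss	figure
Pardosa_lugubris	Loss	figure
Pardosa_amentata	Loss	figure
Arctosa_lutetiana	Loss	figure
Arctosa_alpigena_lamperti	Loss	figure
Argyroneta_aquatica	Loss	figure
Eratigena_atrica	Loss	figure
Hogna_carolinensis	Modified	text
Dolomedes_tenebrosus	Modified	text
Tengella_perfuga	Modified	text
Thaida_peculiaris	Modified	text
Hypochilus_pococki	Modified	text
Phyxelida_tanganensis	Pseudoflagelliform	text
Hyptiotes_paradoxus	Pseudoflagelliform	text
Kukulcania_hibernalis	None	text
Megadictyna_thilenii	None	figure
Nicodamus_mainae	Loss	figure
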