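# 27-taxon topology for ancestral character estimation: the 22 study species
# plus five deeper cribellate/ecribellate lineages (Hypochilus, Kukulcania,
# Thaida, Megadictyna, Nicodamus). Nicodamoidea sister to Araneoidea; the
# other three families outside the Araneoidea + RTA core. Topology only;
# lengths assigned by the loader. See docs/methods.md for reconstruction
# provenance.
(Thaida_peculiaris,((Hypochilus_pococki,Kukulcania_hibernalis),(((Megadictyna_thilenii,Nicodamus_mainae),((Enoplognatha_ovata,(Larinioides_cornutus,(Neoscona_theisi,(Araneus_cavaticus,Araneus_diadematus)))),(Metellina_segmentata,(Mimetus_puritanus,Mimetus_notius)))),(Phyxelida_tanganensis,(Hyptiotes_paradoxus,(Argyroneta_aquatica,(Eratigena_atrica,(Tibellus_oblongus,(Xysticus_cristatus,(Tengella_perfuga,(Dolomedes_tenebrosus,(Xerolycosa_nemoralis,((Pardosa_lugubris,Pardosa_amentata),(Hogna_carolinensis,(Arctosa_lutetiana,Arctosa_alpigena_lamperti)))))))))))))));
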