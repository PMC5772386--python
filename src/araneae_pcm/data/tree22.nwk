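# 22-taxon study topology (PGLS / signal analyses), transcribed from the
# published figure's description and the Araneae Tree of Life relationships
# it follows. Topology only; branch lengths are assigned by the loader
# (Grafen ultrametric or unit). Within-family resolution not stated in the
# source text was reconstructed against the study's printed statistics; see
# docs/methods.md.
(((Enoplognatha_ovata,(Larinioides_cornutus,(Neoscona_theisi,(Araneus_cavaticus,Araneus_diadematus)))),(Metellina_segmentata,(Mimetus_puritanus,Mimetus_notius))),(Phyxelida_tanganensis,(Hyptiotes_paradoxus,(Argyroneta_aquatica,(Eratigena_atrica,(Tibellus_oblongus,(Xysticus_cristatus,(Tengella_perfuga,(Dolomedes_tenebrosus,(Xerolycosa_nemoralis,((Pardosa_lugubris,Pardosa_amentata),(Hogna_carolinensis,(Arctosa_lutetiana,Arctosa_alpigena_lamperti)))))))))))));
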