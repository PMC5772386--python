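# Discrete predictor states of the 27 ACE taxa. For the 22 study species
# the states recode the printed trait-table scores; for the five added taxa
# (not scored in the printed table) the assignments are reconstructions
# from the taxa's described biology (source=reconstructed). Instar is not
# included (the study excluded it from ACE: unavailable for added taxa).
species	Strategy	Specific	Silk	Type	source
Tibellus_oblongus	NoWeb	sit_pursue	none_dragline	std7	table
Xysticus_cristatus	NoWeb	ambush	none_dragline	std7	table
Xerolycosa_nemoralis	NoWeb	active	none_dragline	std7	table
Pardosa_lugubris	NoWeb	active	none_dragline	std7	table
Pardosa_amentata	NoWeb	active	none_dragline	std7	table
Hogna_carolinensis	NoWeb	sit_pursue	none_dragline	std7_ms	table
Arctosa_lutetiana	NoWeb	ambush	burrow	std7	table
Arctosa_alpigena_lamperti	NoWeb	active	none_dragline	std7	table
Dolomedes_tenebrosus	NoWeb	sit_wait	none_dragline	std7_ms	table
Tengella_perfuga	Web	funnel_web	cribellate	std7_ms_flank_crib	table
Argyroneta_aquatica	Web	sheet_web	aciniform_sheet	std7	table
Eratigena_atrica	Web	funnel_web	aciniform_sheet	std7	table
Phyxelida_tanganensis	Web	sheet_web	cribellate	std7_crib_para_pf	table
Hyptiotes_paradoxus	Web	orb_web	cribellate	std7_crib_para_pf	table
Metellina_segmentata	Web	orb_web	viscous	std7_ag_fl	table
Mimetus_puritanus	NoWeb	stalking	none_dragline	std7_mspi	table
Mimetus_notius	NoWeb	stalking	none_dragline	std7_mspi	table
Neoscona_theisi	Web	orb_web	viscous	std7_ag_fl	table
Araneus_cavaticus	Web	orb_web	viscous	std7_ag_fl	table
Araneus_diadematus	Web	orb_web	viscous	std7_ag_fl	table
Larinioides_cornutus	Web	orb_web	viscous	std7_ag_fl	table
Enoplognatha_ovata	Web	tangle_web	viscous	std7_ag_fl	table
Hypochilus_pococki	Web	sheet_web	cribellate	crib_para	reconstructed
Kukulcania_hibernalis	Web	funnel_web	cribellate	crib_para	reconstructed
Thaida_peculiaris	Web	sheet_web	cribellate	crib_para	reconstructed
Megadictyna_thilenii	Web	sheet_web	cribellate	crib_para	reconstructed
Nicodamus_mainae	Web	sheet_web	aciniform_sheet	std7	reconstructed
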