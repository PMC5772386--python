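# Per-species average spigot counts (12 response variables: adult female
# and second instar). SYNTHETIC RECONSTRUCTION: the study's supplementary
# ontogeny dataset is not reproduced in the available text. Values are
# exact where the text states them (Dolomedes/Hogna from the printed
# ontogeny table; adult-female mAP = 1 for araneoids and 2 for all other
# groups; second-instar MAP absent in Tibellus/Xysticus and single in
# Metellina) and realistic inventions elsewhere. Columns: Fem_* = adult
# female, Sec_* = second instar; ALS/PMS/PLS = spinneret; MAP/PI/mAP/AC/CY
# = spigot types. CY spigots exist only in adult females.
species	Fem_ALS_MAP	Fem_ALS_PI	Fem_PMS_mAP	Fem_PMS_AC	Fem_PMS_CY	Fem_PLS_AC	Fem_PLS_CY	Sec_ALS_MAP	Sec_ALS_PI	Sec_PMS_mAP	Sec_PMS_AC	Sec_PLS_AC
Tibellus_oblongus	2	30	2	8	6	10	4	0	4	1	3	3
Xysticus_cristatus	2	25	2	7	5	9	3	0	3	1	3	3
Xerolycosa_nemoralis	2	60	2	20	8	18	6	2	5	2	4	5
Pardosa_lugubris	2	45	2	15	6	14	5	2	4	2	4	4
Pardosa_amentata	2	55	2	18	7	16	5	2	5	2	4	5
Hogna_carolinensis	2	122	2	82	10	43	1	2	4	2	4	7
Arctosa_lutetiana	2	50	2	16	7	15	5	2	4	2	4	4
Arctosa_alpigena_lamperti	2	58	2	19	8	17	6	2	5	2	4	5
Dolomedes_tenebrosus	2	107	2	15	32	24	28	2	6	2	4	4
Tengella_perfuga	2	90	2	30	12	28	10	2	6	2	5	6
Argyroneta_aquatica	2	35	2	12	5	11	4	2	3	1	3	3
Eratigena_atrica	2	70	2	25	9	22	8	2	5	2	4	5
Phyxelida_tanganensis	2	65	2	22	8	20	7	2	4	2	4	4
Hyptiotes_paradoxus	2	20	2	10	4	12	5	2	2	1	3	3
Metellina_segmentata	1.5	28	1	9	6	10	5	1	3	1	3	3
Mimetus_puritanus	1.5	18	1	6	3	7	3	2	2	1	2	2
Mimetus_notius	1.5	16	1	6	3	6	3	2	2	1	2	2
Neoscona_theisi	2	40	1	14	8	16	6	2	4	2	4	4
Araneus_cavaticus	2	55	1	18	10	20	8	2	5	2	4	5
Araneus_diadematus	2	48	1	16	9	18	7	2	4	2	4	4
Larinioides_cornutus	2	38	1	13	8	15	6	2	4	2	4	4
Enoplognatha_ovata	1.5	15	1	8	5	9	4	2	2	1	3	3
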