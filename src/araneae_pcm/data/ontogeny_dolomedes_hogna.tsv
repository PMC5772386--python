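# Full spigot ontogeny of Dolomedes tenebrosus and Hogna carolinensis:
# functional spigot counts by spinneret and instar (printed ontogeny table).
# Stage flags: juvenile, antepenultimate_female, penultimate_male,
# penultimate_female, adult_male, adult_female. Pre-spigots (functionality
# determined but not yet open) are recorded in the note column, not in the
# counts. The adult-female Hogna modified spigot is a tentative
# identification (flagged in note).
species	instar	stage	MAP	PI	mAP	AC_PMS	CY_PMS	AC_PLS	CY_PLS	Modified	note
Dolomedes_tenebrosus	2	juvenile	2	6	2	4	0	4	0	0
Hogna_carolinensis	2	juvenile	2	4	2	4	0	7	0	0
Dolomedes_tenebrosus	3	juvenile	2	9	2	4	0	6	0	0
Hogna_carolinensis	3	juvenile	2	7	2	6	0	9	0	0
Dolomedes_tenebrosus	4	juvenile	2	9	2	5	0	6	0	0
Hogna_carolinensis	4	juvenile	2	11	2	3	0	3	0	0
Dolomedes_tenebrosus	5	juvenile	2	14	2	5	0	6	0	0
Hogna_carolinensis	5	juvenile	2	13	2	3	0	3	0	0
Dolomedes_tenebrosus	6	juvenile	2	16	2	5	0	9	0	0
Hogna_carolinensis	6	juvenile	2	17	2	6	0	7	0	0
Dolomedes_tenebrosus	7	juvenile	2	18	2	6	0	8	0	0
Hogna_carolinensis	7	juvenile	2	27	2	4	0	7	0	0
Dolomedes_tenebrosus	8	juvenile	2	27	2	8	0	9	0	0
Dolomedes_tenebrosus	9	juvenile	2	57	2	8	0	15	0	0
Dolomedes_tenebrosus	10	antepenultimate_female	2	52	2	8	0	10	0	0
Dolomedes_tenebrosus	11	penultimate_male	2	75	2	9	0	14	0	0
Dolomedes_tenebrosus	12	penultimate_female	2	133	2	30	0	42	0	0	pre-CY-PMS:1;pre-CY-PLS:3;pre-Modified:1
Dolomedes_tenebrosus	12	adult_male	1	54	1	7	0	13	0	0
Hogna_carolinensis	12	adult_female	2	122	2	82	10	43	1	1	tentative_modified
Dolomedes_tenebrosus	13	adult_female	2	107	2	15	32	24	28	1
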