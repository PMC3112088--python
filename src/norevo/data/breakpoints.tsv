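# 42 evolutionary breakpoints placed on (segment, branch) with their
# rearrangement class and centromere context. SYNTHETIC transcription of the
# unpublished chromosomal-phylogeny placements; branches are identified by the
# sorted tip set below the branch's child node. centromere_present and the
# scenario columns are transcribed annotations, not reconstruction output.
breakpoint_id	segment	rearrangement	child_clade	centromere_present	sub_position	centromere_fate
bp01	14	translocation	M_pahari	1	between_centromere_and_cluster	lost
bp02	14	fission	M_booduga|M_caroli|M_cervicolor|M_cooki|M_cypriacus|M_famulus|M_fragilicauda|M_haussa|M_indutus|M_m_castaneus|M_m_domesticus|M_m_musculus|M_macedonicus|M_mattheyi|M_minutoides|M_musculoides|M_platythrix|M_spicilegus|M_spretus|M_terricolor	1	between_centromere_and_cluster	lost_then_reacquired
bp03	15p	inversion	Apodemus_sylvaticus	1	distal_end_of_cluster	lost
bp04	15p	fission	M_booduga|M_caroli|M_cervicolor|M_cooki|M_cypriacus|M_famulus|M_fragilicauda|M_haussa|M_indutus|M_m_castaneus|M_m_domesticus|M_m_musculus|M_macedonicus|M_mattheyi|M_minutoides|M_musculoides|M_pahari|M_platythrix|M_spicilegus|M_spretus|M_terricolor	1	distal_end_of_cluster	lost
bp05	16	fusion	Rattus_rattus	1	between_centromere_and_cluster	lost_then_reacquired
bp06	16	translocation	Apodemus_sylvaticus|M_booduga|M_caroli|M_cervicolor|M_cooki|M_cypriacus|M_famulus|M_fragilicauda|M_haussa|M_indutus|M_m_castaneus|M_m_domesticus|M_m_musculus|M_macedonicus|M_mattheyi|M_minutoides|M_musculoides|M_pahari|M_platythrix|M_spicilegus|M_spretus|M_terricolor	1	between_centromere_and_cluster	lost_then_reacquired
bp07	19	fission	M_pahari	1	between_centromere_and_cluster	lost_then_reacquired
bp08	19	fusion	M_booduga|M_caroli|M_cervicolor|M_cooki|M_cypriacus|M_famulus|M_fragilicauda|M_haussa|M_indutus|M_m_castaneus|M_m_domesticus|M_m_musculus|M_macedonicus|M_mattheyi|M_minutoides|M_musculoides|M_platythrix|M_spicilegus|M_spretus|M_terricolor	1	between_centromere_and_cluster	lost
bp09	11d	fission	M_pahari	0		
bp10	11d	fusion	M_booduga|M_caroli|M_cervicolor|M_cooki|M_cypriacus|M_famulus|M_fragilicauda|M_haussa|M_indutus|M_m_castaneus|M_m_domesticus|M_m_musculus|M_macedonicus|M_mattheyi|M_minutoides|M_musculoides|M_platythrix|M_spicilegus|M_spretus|M_terricolor	0		
bp11	13d	inversion	M_caroli|M_cervicolor|M_cooki	0		
bp12	13d	translocation	M_caroli	0		
bp13	1d	fission	M_haussa|M_indutus|M_mattheyi|M_minutoides|M_musculoides	0		
bp14	1d	fusion	M_mattheyi	0		
bp15	2d	inversion	Apodemus_sylvaticus	0		
bp16	2d	translocation	M_booduga|M_caroli|M_cervicolor|M_cooki|M_cypriacus|M_famulus|M_fragilicauda|M_haussa|M_indutus|M_m_castaneus|M_m_domesticus|M_m_musculus|M_macedonicus|M_mattheyi|M_minutoides|M_musculoides|M_pahari|M_platythrix|M_spicilegus|M_spretus|M_terricolor	0		
bp17	5d	fission	Apodemus_sylvaticus	0		
bp18	5d	fusion	M_booduga|M_caroli|M_cervicolor|M_cooki|M_cypriacus|M_famulus|M_fragilicauda|M_haussa|M_indutus|M_m_castaneus|M_m_domesticus|M_m_musculus|M_macedonicus|M_mattheyi|M_minutoides|M_musculoides|M_pahari|M_platythrix|M_spicilegus|M_spretus|M_terricolor	0		
bp19	8d	inversion	M_haussa|M_indutus|M_mattheyi|M_minutoides|M_musculoides	0		
bp20	8d	translocation	M_mattheyi	0		
bp21	11p	fission	M_haussa	0		
bp22	2p	fusion	M_mattheyi	1		
bp23	2p	inversion	M_haussa|M_indutus|M_minutoides|M_musculoides	1		
bp24	3	translocation	M_haussa|M_indutus|M_mattheyi|M_minutoides|M_musculoides	1		
bp25	3	fission	M_mattheyi	1		
bp26	5p	fusion	M_m_castaneus	1		
bp27	5p	inversion	M_m_domesticus|M_m_musculus	1		
bp28	9	translocation	M_haussa|M_indutus|M_mattheyi|M_minutoides|M_musculoides	1		
bp29	9	fission	M_mattheyi	1		
bp30	11d	fusion	M_haussa|M_indutus|M_mattheyi|M_minutoides|M_musculoides	1		
bp31	11d	inversion	M_mattheyi	1		
bp32	11p	translocation	M_indutus|M_minutoides|M_musculoides	1		
bp33	11p	fission	M_indutus	1		
bp34	10p	fission	Rattus_rattus	0		
bp35	10p	fusion	Apodemus_sylvaticus|M_booduga|M_caroli|M_cervicolor|M_cooki|M_cypriacus|M_famulus|M_fragilicauda|M_haussa|M_indutus|M_m_castaneus|M_m_domesticus|M_m_musculus|M_macedonicus|M_mattheyi|M_minutoides|M_musculoides|M_pahari|M_platythrix|M_spicilegus|M_spretus|M_terricolor	1		
bp36	13d	inversion	Rattus_rattus	0		
bp37	13d	translocation	Apodemus_sylvaticus|M_booduga|M_caroli|M_cervicolor|M_cooki|M_cypriacus|M_famulus|M_fragilicauda|M_haussa|M_indutus|M_m_castaneus|M_m_domesticus|M_m_musculus|M_macedonicus|M_mattheyi|M_minutoides|M_musculoides|M_pahari|M_platythrix|M_spicilegus|M_spretus|M_terricolor	1		
bp38	17p	fission	Rattus_rattus	0		
bp39	17p	fusion	Apodemus_sylvaticus|M_booduga|M_caroli|M_cervicolor|M_cooki|M_cypriacus|M_famulus|M_fragilicauda|M_haussa|M_indutus|M_m_castaneus|M_m_domesticus|M_m_musculus|M_macedonicus|M_mattheyi|M_minutoides|M_musculoides|M_pahari|M_platythrix|M_spicilegus|M_spretus|M_terricolor	1		
bp40	5p	inversion	Rattus_rattus	0		
bp41	5p	translocation	Apodemus_sylvaticus|M_booduga|M_caroli|M_cervicolor|M_cooki|M_cypriacus|M_famulus|M_fragilicauda|M_haussa|M_indutus|M_m_castaneus|M_m_domesticus|M_m_musculus|M_macedonicus|M_mattheyi|M_minutoides|M_musculoides|M_pahari|M_platythrix|M_spicilegus|M_spretus|M_terricolor	1		
bp42	8p	fission	Rattus_rattus	0		
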