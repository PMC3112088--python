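# Centromere presence (1/0, ? = unknown) per taxon and orthologous segment.
# SYNTHETIC transcription standing in for the unpublished chromosomal
# phylogeny annotations; editable. See docs/methods.md for the rules used.
taxon	1p	1d	2p	2d	3	4	5p	5m	5d	6	7	8p	8d	9	10p	10d	11p	11d	12	12d	13p	13d	14	15p	15d	16	17p	17d	18	19
Rattus_rattus	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	1	0	1	0
Apodemus_sylvaticus	?	?	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	1	1	0	1	1	1	1	1	0	1	0
M_pahari	1	1	1	0	1	1	1	1	0	1	1	1	1	1	1	0	1	0	1	0	1	0	1	1	0	1	1	1	1	0
M_platythrix	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	1	0	1	0
M_mattheyi	1	0	1	1	1	1	1	0	1	1	1	1	0	1	1	0	1	1	1	0	1	1	1	1	1	1	1	0	1	0
M_musculoides	1	0	1	1	1	1	1	0	1	1	1	1	0	1	1	0	1	1	1	0	1	0	1	1	0	1	1	0	1	0
M_minutoides	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	1	1	0	1	1	1	1	0	1	0	0	1	0
M_indutus	1	0	1	1	1	1	1	0	1	1	1	1	0	1	1	0	1	1	1	0	1	1	1	1	1	1	1	0	1	0
M_haussa	1	0	1	1	1	1	1	0	1	1	1	1	0	1	1	0	1	1	1	0	1	1	1	1	1	1	1	0	1	0
M_caroli	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	1	0	1	1
M_cervicolor	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	1	0	1	1
M_cooki	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	1	0	1	1
M_fragilicauda	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	1	0	1	1
M_famulus	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	1	0	1	1
M_spicilegus	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	0	0	1	1
M_spretus	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	0	0	1	1
M_macedonicus	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	0	0	1	1
M_cypriacus	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	1	0	1	1
M_m_castaneus	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	0	0	1	1
M_m_musculus	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	1	0	1	1
M_m_domesticus	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	0	0	1	1
M_booduga	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	1	0	1	1
M_terricolor	1	0	1	0	1	1	1	0	0	1	1	1	0	1	1	0	1	0	1	0	1	0	1	1	0	1	1	0	1	1
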