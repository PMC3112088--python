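# Chromosomal distribution of 18S-28S rDNA clusters per taxon.
# Token notation: bare label = pericentromeric cluster; trailing * = subtelomeric;
# trailing ~ = between centromere and telomere; a.b = Robertsonian metacentric
# (cluster scored on both arms).
taxon	subgenus	diploid_2n	chromosomes
Rattus_rattus	Outgroup	38	5,8,16
Apodemus_sylvaticus	Outgroup	48	7*,8*,11*,12*,15*,16*,21*,22*
M_pahari	Coelomys	48	1,2,3,4,5,7,8,10,11,12,13,14,15,16,17,18,19,20,21,22,23
M_platythrix	Pyromys	26	5,8,12
M_mattheyi	Nannomys	36	1,4,8,11,13,14,17
M_musculoides	Nannomys	18	4.13,8.15
M_minutoides	Nannomys	18	4.7,12.17,13.16,14.15
M_indutus	Nannomys	36	14,15,17
M_haussa	Nannomys	36	15
M_caroli	Mus	40	1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,X
M_cervicolor	Mus	40	4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19
M_cooki	Mus	40	7,8,9,10,11,12,13,14,15,16,17,18,19
M_fragilicauda	Mus	40	1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19
M_famulus	Mus	40	2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19
M_spicilegus	Mus	40	5,6,8,16,19
M_spretus	Mus	40	4*,13*,19*
M_macedonicus	Mus	40	3,4,5,8,12,16,19
M_cypriacus	Mus	40	1,4,11,15,16,17,18,19
M_m_castaneus	Mus	40	4,8,9,10,11,12,15,16,18,19
M_m_musculus	Mus	40	4,8,10,11,12,15,16,17,19
M_m_domesticus	Mus	40	12,15,16,18,19,4*
M_booduga	Mus	40	1,3,4,6,8,9,11,12,13,14,15,16,17,18
M_terricolor	Mus	40	4~,6~,7~,12~,15~,17~,18~,19~
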