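(Rattus_rattus:1.0,(Apodemus_sylvaticus:0.85,(M_pahari:0.62,((M_mattheyi:0.4,(M_haussa:0.32,(M_indutus:0.26,(M_musculoides:0.18,M_minutoides:0.18):0.08):0.06):0.08):0.14,(M_platythrix:0.48,((M_caroli:0.28,(M_cervicolor:0.2,M_cooki:0.2):0.08):0.12,((M_terricolor:0.28,(M_booduga:0.22,(M_fragilicauda:0.16,M_famulus:0.16):0.06):0.06):0.08,(M_spretus:0.26,(M_spicilegus:0.22,((M_macedonicus:0.12,M_cypriacus:0.12):0.06,(M_m_castaneus:0.12,(M_m_musculus:0.07,M_m_domesticus:0.07):0.05):0.06):0.04):0.04):0.1):0.04):0.08):0.06):0.08):0.23):0.15);
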