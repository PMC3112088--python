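# Chromosome -> orthologous-segment homology map (30 ancestral segments).
# House-mouse (subgenus Mus) labels are the segment nomenclature itself; rows for
# the other subgenera and the outgroups are a SYNTHETIC transcription standing in
# for the unpublished Zoo-FISH comparative maps, editable here. Segment "." marks
# chromosomes outside the 30 autosomal segments (the X). "missing" rows list
# segments whose cluster state is unknowable for a taxon and coded "?".
scope	kind	chromosome	proximal_segment	distal_segment
subgenus:Mus	map	1	1p	1d
subgenus:Mus	map	2	2p	2d
subgenus:Mus	map	3	3	3
subgenus:Mus	map	4	4	4
subgenus:Mus	map	5	5p	5d
subgenus:Mus	map	6	6	6
subgenus:Mus	map	7	7	7
subgenus:Mus	map	8	8p	8d
subgenus:Mus	map	9	9	9
subgenus:Mus	map	10	10p	10d
subgenus:Mus	map	11	11p	11d
subgenus:Mus	map	12	12	12d
subgenus:Mus	map	13	13p	13d
subgenus:Mus	map	14	14	14
subgenus:Mus	map	15	15p	15d
subgenus:Mus	map	16	16	16
subgenus:Mus	map	17	17p	17d
subgenus:Mus	map	18	18	18
subgenus:Mus	map	19	19	19
subgenus:Mus	map	X	.	.
subgenus:Nannomys	map	1	1p	1p
subgenus:Nannomys	map	4	4	4
subgenus:Nannomys	map	7	2d	2d
subgenus:Nannomys	map	8	8p	8p
subgenus:Nannomys	map	11	11d	11d
subgenus:Nannomys	map	12	12	12
subgenus:Nannomys	map	13	13d	13d
subgenus:Nannomys	map	14	14	14
subgenus:Nannomys	map	15	15d	15d
subgenus:Nannomys	map	16	5d	5d
subgenus:Nannomys	map	17	17p	17p
subgenus:Coelomys	map	1	1p	1p
subgenus:Coelomys	map	2	2p	2p
subgenus:Coelomys	map	3	3	3
subgenus:Coelomys	map	4	4	4
subgenus:Coelomys	map	5	5p	5p
subgenus:Coelomys	map	6	6	6
subgenus:Coelomys	map	7	7	7
subgenus:Coelomys	map	8	8p	8p
subgenus:Coelomys	map	9	9	9
subgenus:Coelomys	map	10	10p	10p
subgenus:Coelomys	map	11	11p	11p
subgenus:Coelomys	map	12	12	12
subgenus:Coelomys	map	13	13p	13p
subgenus:Coelomys	map	14	14	14
subgenus:Coelomys	map	15	15p	15p
subgenus:Coelomys	map	16	16	16
subgenus:Coelomys	map	17	17p	17p
subgenus:Coelomys	map	18	18	18
subgenus:Coelomys	map	19	19	19
subgenus:Coelomys	map	20	1d	1d
subgenus:Coelomys	map	21	5m	5m
subgenus:Coelomys	map	22	8d	8d
subgenus:Coelomys	map	23	17d	17d
subgenus:Pyromys	map	5	5p	5p
subgenus:Pyromys	map	8	8p	8p
subgenus:Pyromys	map	12	12	12
taxon:Rattus_rattus	map	5	5p	5p
taxon:Rattus_rattus	map	8	8p	8p
taxon:Rattus_rattus	map	16	16	16
taxon:Apodemus_sylvaticus	map	7	3	3
taxon:Apodemus_sylvaticus	map	8	6	6
taxon:Apodemus_sylvaticus	map	11	9	9
taxon:Apodemus_sylvaticus	map	12	12d	12d
taxon:Apodemus_sylvaticus	map	15	15d	15d
taxon:Apodemus_sylvaticus	map	16	16	16
taxon:Apodemus_sylvaticus	map	21	18	18
taxon:Apodemus_sylvaticus	map	22	19	19
taxon:Apodemus_sylvaticus	missing		1p,1d
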