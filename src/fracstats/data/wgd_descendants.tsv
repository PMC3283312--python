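# Summary data for 15 WGD-descendant genomes (6 distinct WGD events).
# Columns: genome; t_mya (approximate time since WGD, metadata only); n (total genes);
# m (single-copy genes); one_minus_theta (printed proportion of ancestral loci reduced
# to single copy); u_bar (observed mean single-copy AU run length).  The rearrangement
# distance d is not printed in the source table and is supplied by the user when needed.
genome	t_mya	n	m	one_minus_theta	u_bar
S. cerevisiae	150	5616	4498	0.89	6.0958
C. glabrata	150	5180	4382	0.92	5.3839
V. polyspora	150	5112	4164	0.9	4.922
S. bayanus	150	5857	4773	0.9	5.8297
N. castelli	150	5213	4053	0.88	5.0717
Paramecium	20	38626	14576	0.55	2.0299
populus	70	20082	7228	0.53	1.6402
Arabidopsis	50	25655	13267	0.68	3.6086
fugu	350	14251	12653	0.941	3.806
medaka	350	14564	13352	0.957	5.0629
stickleback	350	16726	14876	0.941	4.3792
tetraodon	350	17120	16088	0.969	6.876
chicken	450	10077	8495	0.915	3.6122
opossum	450	13339	11589	0.93	5.5507
human	450	13828	12144	0.935	3.818
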