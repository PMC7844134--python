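genome_id	accession	n_contigs	genome_size_bp	gc_pct	completeness	contamination
ES-bin-14	GCA_014380785.1	633	5349535	60.2	79.18	6.59
ES-bin-29	GCA_014379705.1	758	5043933	67.5	67.91	1.1
ES-bin-51	GCA_014379355.1	293	4821585	65.3	83.65	2.39
ES-bin-78	GCA_014379205.1	339	4113156	60.3	89.05	7.69
LF-bin-215	GCA_014378185.1	808	3680986	65.7	73.65	4.4
LF-bin-339	GCA_014377535.1	254	3787951	65.7	90.61	3.3
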