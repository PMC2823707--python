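# Loop free-energy penalties for RNA secondary structure, dG at 37 C (kcal/mol).
# Same grammar as loops_dna.tsv.
hairpin	3	5.4
hairpin	4	5.6
hairpin	5	5.7
hairpin	6	5.4
hairpin	7	6.0
hairpin	8	5.5
hairpin	9	6.4
hairpin	10	6.5
hairpin	12	6.7
hairpin	14	6.9
hairpin	16	7.1
hairpin	18	7.2
hairpin	20	7.3
hairpin	25	7.6
hairpin	30	7.7
bulge	1	3.8
bulge	2	2.8
bulge	3	3.2
bulge	4	3.6
bulge	5	4.0
bulge	6	4.4
bulge	7	4.6
bulge	8	4.7
bulge	9	4.8
bulge	10	4.9
bulge	12	5.2
bulge	14	5.4
bulge	16	5.6
bulge	18	5.8
bulge	20	5.9
bulge	25	6.3
bulge	30	6.6
internal	2	2.3
internal	3	2.5
internal	4	2.7
internal	5	3.0
internal	6	3.3
internal	7	3.6
internal	8	3.8
internal	9	4.0
internal	10	4.2
internal	12	4.5
internal	14	4.8
internal	16	5.0
internal	18	5.2
internal	20	5.4
internal	25	5.8
internal	30	6.1
multiloop	3.4	0.4	0.0
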