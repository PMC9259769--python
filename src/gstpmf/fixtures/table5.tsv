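# Lys-C peptide table for the BaGST2 reconstruction: 17 fragments with
# HPLC-measured masses (Da, [M+H]+ reading), missed-cleavage counts (NM),
# printed 1-based position intervals, sequences and the source taxon of the
# database peptide each fragment matched. anchor_kind 'edman' marks the three
# fragments sequenced directly on a gas-phase sequencer (their masses carry
# two decimals and no separately printed NM; the NM stored here is computed
# from the sequence). flags record internal inconsistencies of the printed
# table, preserved verbatim rather than repaired.
peptide_no	mass_da	nm	start	end	sequence	source	anchor_kind	flags
1	890.4	1	1	8	MAEAKNVK	Sphingomonas	mass_match	
2	2465.5	1	9	30	VLYFDVTGLGEILRLLLKFAGK	B. glabrata	mass_match	
3	1859.90	0	31	44	EYEDVRFSFEEWPK	B. glabrata	edman	edman
4	1843.0	1	47	63	PTTPFGQMPVLEVDGKK	Copidosoma floridanum	mass_match	
5	1635.9	0	65	79	AQSIALAAFLAREFK	B. glabrata	mass_match	
6	2338.2	0	84	104	DDLEALQVDATVDTIHDLRAK	Dufourea novaeangliae	mass_match	
7	1065.6	0	108	115	SFRESDPVK	B. glabrata	mass_match	interval_shorter_than_sequence
8	1495.5	1	105	115	RFKSFRESDPVK	B. glabrata	mass_match	interval_shorter_than_sequence
9	888.62	0	116	123	EAIVTEVK	B. glabrata	edman	edman
10	1345.8	1	130	140	FMGFFESLLKK	B. glabrata	mass_match	
11	979.5	0	143	152	NGSTGLFVGK	Haliotis discus discus	mass_match	
12	1235.7	2	142	150	KNGSTGLFVGKK	Haliotis discus	mass_match	interval_shorter_than_sequence
13	1057.5	1	140	149	NGGHFVNGKK	Ooceraea biroi	mass_match	
14	1864.0	0	154	169	LTWGDFVFAGIYAYLK	Epiphyas postvittana	mass_match	
15	1434.80	0	170	182	AAFEAIDNFPLVK	B. glabrata	edman	edman
16	1358.7	0	183	194	LVDTVGDNERIK	B. glabrata	mass_match	
17	1234.6	1	195	206	WIETRPASKF	Haemonchus contortus	mass_match	interval_longer_than_sequence
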