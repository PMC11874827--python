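# glyph specifications per canonical type, version 1
category	type_key	display_name	glyph_id	colour	head_style
region	domain	Domain	1	auto	none
region	repeat	Repeat	2	auto	none
region	region	Region	3	auto	none
motif	signal_peptide	Signal peptide	1	#D94C4C	none
motif	coiled_coil	Coiled coil	2	#D97E4C	none
motif	low_complexity	Low complexity	3	#D9AF4C	none
motif	disorder	Intrinsic disorder	4	#D0D94C	none
motif	disordered_binding	Intrinsically disordered binding	5	#9FD94C	none
motif	charged_polar_patch	Charged or polar patch	6	#6DD94C	none
motif	phosphorylation_motif	Phosphorylation motif	7	#4CD95C	none
motif	glycosylation_motif	Glycosylation motif	8	#4CD98E	none
motif	transmembrane	Transmembrane part	9	#4CD9C0	none
motif	lipidation_motif	Lipidation motif	10	#4CC0D9	none
motif	cleavage_motif	Cleavage motif	11	#4C8ED9	none
motif	degradation_motif	Degradation motif	12	#4C5CD9	none
motif	targeting_motif	Targeting motif	13	#6D4CD9	none
motif	nuclear_motif	Nuclear localisation or export motif	14	#9F4CD9	none
motif	binding_motif	Docking, ligand or binding motif	15	#D04CD9	none
motif	activity_motif	Activity-related motif	16	#D94CAF	none
motif	other_motif	Other motif	17	#D94C7E	none
markup	n_glycosylation	N-glycosylation	1	#BF3030	circle
markup	o_glycosylation	O-glycosylation	2	#BF4230	square
markup	glycosaminoglycan	Glycosaminoglycan	3	#BF5430	diamond
markup	c_mannosylation	C-mannosylation	4	#BF6730	arrow
markup	o_fucosylation	O-fucosylation	5	#BF7930	pentagon
markup	glycosylation	Glycosylation unspecified	6	#BF8B30	line
markup	hydroxylation	Hydroxylation	7	#BF9E30	circle
markup	prenylation	Prenylated	8	#BFB030	square
markup	acylation	Acylated	9	#BCBF30	diamond
markup	gpi_anchor	GPI anchor	10	#AABF30	arrow
markup	lipidation	Lipidation	11	#98BF30	pentagon
markup	acetylation	Acetylation	12	#85BF30	line
markup	methylation	Methylation	13	#73BF30	circle
markup	amidation	Amidation	14	#61BF30	square
markup	pyrrolidone_carboxylic_acid	Pyrrolidone carboxylic acid	15	#4EBF30	diamond
markup	sulfation	Sulfation	16	#3CBF30	arrow
markup	d_isomerization	D-isomerization	17	#30BF36	pentagon
markup	disulfide_bond	Di-sulfide bond	18	#30BF48	line
markup	cross_link	Cross-linking	19	#30BF5B	circle
markup	sumoylation	Sumoylation	20	#30BF6D	square
markup	ubiquitination	Ubiquitination	21	#30BF7F	diamond
markup	degradation	Degradation	22	#30BF91	arrow
markup	cleavage	Cleavage	23	#30BFA4	pentagon
markup	sorting	Sorting	24	#30BFB6	line
markup	targeting	Targeting	25	#30B6BF	circle
markup	retaining	Retaining	26	#30A4BF	square
markup	absorption	Absorption	27	#3091BF	diamond
markup	nuclear_import	Nuclear import	28	#307FBF	arrow
markup	nuclear_export	Nuclear export	29	#306DBF	pentagon
markup	nuclear_receptor	Nuclear receptor	30	#305BBF	line
markup	nuclear_related	Nuclear-related	31	#3048BF	circle
markup	dna_binding	DNA-binding	32	#3036BF	square
markup	binding_site	Binding site	33	#3C30BF	diamond
markup	ligand_binding	Ligand binding	34	#4E30BF	arrow
markup	ligand_site	Ligand site	35	#6130BF	pentagon
markup	docking	Docking	36	#7330BF	line
markup	interaction	Interacts with	37	#8530BF	circle
markup	flavin_binding	Flavin-binding	38	#9830BF	square
markup	cofactor	Co-factor	39	#AA30BF	diamond
markup	active_site	Active site	40	#BC30BF	arrow
markup	catalytic_activity	Catalytic activity	41	#BF30B0	pentagon
markup	activity_regulation	Activity regulation	42	#BF309E	line
markup	phospho_serine	Phospho-serine	43	#BF308B	circle
markup	phospho_threonine	Phospho-threonine	44	#BF3079	square
markup	phospho_tyrosine	Phospho-tyrosine	45	#BF3067	diamond
markup	phosphorylation	Phosphorylation unspecified	46	#BF3054	arrow
markup	other	Other	47	#BF3042	pentagon
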