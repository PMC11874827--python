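# keyword-pattern vocabulary, dialect version 1
pattern	category	type_key
domain	region	domain
zn_fing	region	domain
zinc finger	region	domain
repeat	region	repeat
region	region	region
dna-binding region	region	region
signal peptide	motif	signal_peptide
sig_peptide	motif	signal_peptide
signal	motif	signal_peptide
coiled coil	motif	coiled_coil
coiled-coil	motif	coiled_coil
coiled	motif	coiled_coil
low complexity	motif	low_complexity
low-complexity	motif	low_complexity
intrinsic disorder	motif	disorder
disorder	motif	disorder
iupred	motif	disorder
unstructured	motif	disorder
disordered binding	motif	disordered_binding
disordered-binding	motif	disordered_binding
anchor	motif	disordered_binding
polar	motif	charged_polar_patch
charged	motif	charged_polar_patch
compbias	motif	charged_polar_patch
compositional bias	motif	charged_polar_patch
basic and acidic	motif	charged_polar_patch
phosphorylation motif	motif	phosphorylation_motif
mod_	motif	phosphorylation_motif
glycosylation motif	motif	glycosylation_motif
mod_n-glc	motif	glycosylation_motif
mod_og	motif	glycosylation_motif
transmembrane	motif	transmembrane
transmem	motif	transmembrane
tm helix	motif	transmembrane
intramem	motif	transmembrane
lipidation motif	motif	lipidation_motif
cleavage motif	motif	cleavage_motif
clv_	motif	cleavage_motif
propep	motif	cleavage_motif
degradation motif	motif	degradation_motif
deg_	motif	degradation_motif
degron	motif	degradation_motif
targeting motif	motif	targeting_motif
trg_	motif	targeting_motif
transit peptide	motif	targeting_motif
transit	motif	targeting_motif
nuclear localisation	motif	nuclear_motif
nuclear localization	motif	nuclear_motif
nuclear export	motif	nuclear_motif
nuclear	motif	nuclear_motif
binding motif	motif	binding_motif
docking motif	motif	binding_motif
ligand motif	motif	binding_motif
lig_	motif	binding_motif
doc_	motif	binding_motif
activity motif	motif	activity_motif
activity-related	motif	activity_motif
motif	motif	other_motif
slim	motif	other_motif
n-linked	markup	n_glycosylation
n-glycosylation	markup	n_glycosylation
n-glyc	markup	n_glycosylation
netnglyc	markup	n_glycosylation
o-linked	markup	o_glycosylation
o-glycosylation	markup	o_glycosylation
o-glyc	markup	o_glycosylation
netoglyc	markup	o_glycosylation
glycosaminoglycan	markup	glycosaminoglycan
xylose	markup	glycosaminoglycan
c-linked	markup	c_mannosylation
c-mannos	markup	c_mannosylation
fucos	markup	o_fucosylation
carboh	markup	glycosylation
glycos	markup	glycosylation
glycation	markup	glycosylation
hydroxy	markup	hydroxylation
prenyl	markup	prenylation
farnesyl	markup	prenylation
geranyl	markup	prenylation
acylat	markup	acylation
palmitoyl	markup	acylation
myristoyl	markup	acylation
gpi-anchor	markup	gpi_anchor
gpi anchor	markup	gpi_anchor
gpi	markup	gpi_anchor
lipid	markup	lipidation
acetyl	markup	acetylation
methyl	markup	methylation
amidat	markup	amidation
pyrrolidone	markup	pyrrolidone_carboxylic_acid
sulfat	markup	sulfation
sulfo	markup	sulfation
d-isomer	markup	d_isomerization
isomeriz	markup	d_isomerization
disulfid	markup	disulfide_bond
disulphide	markup	disulfide_bond
di-sulfide	markup	disulfide_bond
cross-link	markup	cross_link
crosslnk	markup	cross_link
crosslink	markup	cross_link
isopeptide	markup	cross_link
sumo	markup	sumoylation
ubiquitin	markup	ubiquitination
degradation	markup	degradation
cleavage	markup	cleavage
sorting	markup	sorting
targeting	markup	targeting
retention	markup	retaining
retaining	markup	retaining
absorption	markup	absorption
nuclear import	markup	nuclear_import
nuclear export	markup	nuclear_export
nuclear receptor	markup	nuclear_receptor
nuclear	markup	nuclear_related
dna-binding	markup	dna_binding
dna_bind	markup	dna_binding
dna bind	markup	dna_binding
binding site	markup	binding_site
binding	markup	binding_site
ligand binding	markup	ligand_binding
ligand-binding	markup	ligand_binding
ligand site	markup	ligand_site
ligand	markup	ligand_site
metal	markup	ligand_site
docking	markup	docking
interacts with	markup	interaction
interaction	markup	interaction
flavin	markup	flavin_binding
flavin-binding	markup	flavin_binding
fad-binding	markup	flavin_binding
fmn-binding	markup	flavin_binding
cofactor	markup	cofactor
co-factor	markup	cofactor
active site	markup	active_site
act_site	markup	active_site
active	markup	active_site
catalytic	markup	catalytic_activity
activity regulation	markup	activity_regulation
autoinhibit	markup	activity_regulation
phosphoserine	markup	phospho_serine
phospho-serine	markup	phospho_serine
phosphothreonine	markup	phospho_threonine
phospho-threonine	markup	phospho_threonine
phosphotyrosine	markup	phospho_tyrosine
phospho-tyrosine	markup	phospho_tyrosine
phospho	markup	phosphorylation
netphos	markup	phosphorylation
mod_res	markup	other
modified	markup	other
site	markup	other
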