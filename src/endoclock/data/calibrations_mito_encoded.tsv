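# Fossil calibrations used for the mitochondria-encoded alignment: four
# eukaryotic calibration points inside the mitochondrial (host) subtree plus a
# broad root bracket.  Bounds in Ma; both bounds soft with 2.5% tail mass.
# The taxa columns list representative leaves; when applying to a tree the
# clade is resolved as the MRCA (crown) or its parent (total/stem group).
clade_name	taxa	group	t_min	t_max	p_lower	p_upper
crown_angiosperms	Arabidopsis_thaliana;Oryza_sativa	crown	125	250	0.025	0.025
crown_land_plants	Arabidopsis_thaliana;Marchantia_polymorpha	crown	450	509	0.025	0.025
total_florideophyceae	Chondrus_crispus;Gracilaria_changii	total	550	1891	0.025	0.025
total_red_algae	Chondrus_crispus;Cyanidioschyzon_merolae	total	1033	1891	0.025	0.025
root	Arabidopsis_thaliana;Rickettsia_prowazekii	crown	1000	3000	0.025	0.025
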