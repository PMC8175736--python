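# Fossil calibrations used for the nuclear-encoded alignment: the four
# Archaeplastida points of the mito-encoded set plus six additional eukaryotic
# calibrations (animals, fungi, rhizarians) and the root bracket.  Bounds in
# Ma; both bounds soft with 2.5% tail mass.
clade_name	taxa	group	t_min	t_max	p_lower	p_upper
crown_angiosperms	Arabidopsis_thaliana;Oryza_sativa	crown	125	250	0.025	0.025
crown_land_plants	Arabidopsis_thaliana;Marchantia_polymorpha	crown	450	509	0.025	0.025
total_florideophyceae	Chondrus_crispus;Gracilaria_changii	total	550	1891	0.025	0.025
total_red_algae	Chondrus_crispus;Cyanidioschyzon_merolae	total	1033	1891	0.025	0.025
crown_foraminifera	Globobulimina_turgida;Reticulomyxa_filosa	crown	525	1891	0.025	0.025
crown_amniota	Homo_sapiens;Gallus_gallus	crown	318	332	0.025	0.025
crown_chordata	Homo_sapiens;Branchiostoma_floridae	crown	520	636	0.025	0.025
crown_metazoa	Homo_sapiens;Amphimedon_queenslandica	crown	550	833	0.025	0.025
total_fungi	Saccharomyces_cerevisiae;Rozella_allomycis	total	890	1891	0.025	0.025
crown_dikarya	Saccharomyces_cerevisiae;Ustilago_maydis	crown	400	1891	0.025	0.025
root	Arabidopsis_thaliana;Rickettsia_prowazekii	crown	1000	3000	0.025	0.025
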