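gene	group	known_function	gcl_p3	gcl_consistent	brn3a_target_p3	brn3a_target_any	onset	peak	offset	sparse	brn3a_independent_transcripts	gene_level_regulation
Foxp2	transcriptional_translational	TF	yes	no	no	yes	P0	P7	none	no	no	yes
Tshz2	transcriptional_translational	TF	yes	yes	yes	yes	P3	P7	none	no	no	yes
Rbfox1	transcriptional_translational	Splicing of neuronal genes	yes	no	no	no	P0	P14	none	no	yes	no
Eml1	signaling_cytoskeleton	Microtubule-binding protein	yes	no	no	no	P0	P7	none	no	yes	no
Hpca	signaling_cytoskeleton	Calcium sensor	yes	yes	no	yes	P0	P7-P14	none	no	yes	no
Plppr3	signaling_cytoskeleton	Neurite growth and regeneration	yes	yes	no	yes	P0	P0	none	no	no	no
Mapk10	signaling_cytoskeleton	Axonal growth and neuronal survival	yes	yes	no	yes	P0	P7-P14	none	yes	yes	no
Pip5kl1	signaling_cytoskeleton	Cell morphology and adhesion	no	no	no	no	P3	P7	none	no	no	no
Pak6	signaling_cytoskeleton	Signaling kinase	no	no	no	no	none	none	none	no	no	na
Ankrd13b	vesicle_associated	Caveolin-mediated endosomal traffick	yes	yes	no	no	P0	P7	none	no	no	no
Pick1	vesicle_associated	Glutamate receptor trafficking	yes	no	no	no	P0	none	none	no	yes	no
Snap91	vesicle_associated	Clathrin-mediated endocytosis	yes	yes	yes	yes	P0	P7-P14	none	yes	yes	no
Tusc5	vesicle_associated	Insulin-stimulated glucose transport	yes	yes	yes	yes	P3	P14	none	yes	no	yes
Elfn1	synapse_associated	Synaptic adhesion protein	yes	no	no	yes	P3	P7	none	yes	no	yes
Gabra1	synapse_associated	GABA receptor alpha1 subunit	no	no	no	yes	P3	none	none	yes	no	yes
Grm4	synapse_associated	Metabotropic glutamate receptor	yes	no	no	no	P0	P7	none	no	no	yes
Ntrk1	synapse_associated	Neurotrophin receptor	yes	no	no	no	P0	P14-P22	none	no	no	yes
Pnkd	synapse_associated	Synaptic vesicle release	no	yes	no	no	P0	P7-P14	none	yes	yes	no
Rims1	synapse_associated	Synaptic vesicle release & recycling	yes	yes	no	yes	P0	P0-P3	none	yes	no	no
Fam19a4	secreted	Unknown	no	no	no	no	P3	P3-P7	P7	no	no	yes
Nptx1	secreted	Trans-synaptic, excitatory synapse	yes	yes	no	yes	P0	P14	none	yes	no	yes
Nptx2	secreted	Trans-synaptic, excitatory synapse	yes	no	no	no	P3	P7-P14	none	yes	no	yes
Sez6l2	secreted	Synapse formation	yes	yes	no	yes	P3	P7	none	no	yes	no
Cdh4	adhesion_transmembrane	Cell adhesion molecule	yes	no	yes	yes	P0	none	none	yes	no	yes
Pcdh20	adhesion_transmembrane	Cell adhesion molecule	no	no	no	yes	P14	none	none	no	no	yes
Rtn4rl2	adhesion_transmembrane	Axon guidance molecule	yes	yes	no	yes	P0	none	P22	no	no	no
Tmem25	adhesion_transmembrane	Unknown	no	no	no	no	P0	P7-P14	none	no	no	no
Tmem91	adhesion_transmembrane	Unknown	no	no	no	yes	P0	P7-P14	none	no	yes	no
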