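# Pfam domains diagnostic of MGE replication or mobilization (best-effort
# curated list). replication=1 marks the plasmid-replication subset.
# columns: pfam_id, name, replication
pfam_id	name	replication
PF01051	Rep_3	1
PF01446	Rep_1	1
PF01719	Plasmid_Rep	1
PF06970	RepA_N	1
PF04796	RepL	1
PF01076	Mob_Pre	0
PF03432	Relaxase	0
PF00589	Phage_integrase	0
PF00665	rve	0
PF01527	HTH_Tnp_1	0
PF00239	Resolvase	0
PF02371	Transposase_20	0
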