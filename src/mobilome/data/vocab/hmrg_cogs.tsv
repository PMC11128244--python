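# Heavy-metal-resistance COGs. Best-effort curated transcription from the
# public COG database; ids without a canonical COG mapping (cusF, chrB1,
# tehB) are best-effort assignments. Users may override via --vocab.
# columns: cog_id, gene_name, metals (comma-joined)
cog_id	gene_name	metals
COG0789	merR	Hg
COG1249	merA	Hg
COG2217	zntA	Zn,Cd,Pb
COG0053	czcD	Zn,Co,Cd
COG3696	cusA	Cu,Ag
COG4454	cusF	Cu,Ag
COG2608	copZ	Cu
COG1276	pcoB	Cu
COG2132	cueO	Cu
COG2059	chrA	Cr
COG4275	chrB1	Cr
COG0640	arsR	As
COG1055	arsB	As
COG0798	acr3	As
COG1393	arsC	As
COG0003	arsA	As,Sb
COG0861	terC	Te
COG2310	terD	Te
COG3853	telA	Te
COG2226	tehB	Te
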