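# Conjugal-transfer-system COGs found on conjugative (self-transmissible)
# plasmids and integrative and conjugative elements (best-effort curated
# transcription from the public COG database).
# columns: cog_id, gene_name
cog_id	gene_name
COG3451	virB4
COG0630	virB11
COG3505	virD4
COG3846	trbL
COG2948	virB10
COG3504	virB9
COG3702	virB3
COG3736	virB8
COG3843	virD2
COG3598	traA
COG4959	traF
COG4929	traU
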