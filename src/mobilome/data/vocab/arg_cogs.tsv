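# Antibiotic-resistance COGs (best-effort curated transcription from the
# public COG database).
# columns: cog_id, gene_name
cog_id	gene_name
COG1680	ampC
COG0841	acrB
COG1566	emrA
COG3231	aph
COG0577	salY
COG1132	mdlB
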