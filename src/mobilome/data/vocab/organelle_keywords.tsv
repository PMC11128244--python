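# Tokens marking organellar (mitochondrial/chloroplast) gene products or
# eukaryotic lineages; used to screen out partial organelle genomes that
# were inappropriately circularized.
# columns: keyword
keyword
mitochondri
chloroplast
plastid
thylakoid
photosystem
rubisco
cytochrome b6
Eukaryota
Streptophyta
Chlorophyta
Bacillariophyta
Ascomycota
Basidiomycota
Metazoa
Chordata
Arthropoda
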