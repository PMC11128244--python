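# Tokens marking genes involved in viral replication, structure, or
# function; genes matching any token are excluded from AMG calling.
# columns: keyword
keyword
capsid
terminase
portal
tail
baseplate
virion
holin
lysin
endolysin
lysozyme
spike
tape measure
head
scaffold
packaging
integrase
excisionase
recombinase
polymerase
primase
helicase
replication
antirepressor
lysogen
phage
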