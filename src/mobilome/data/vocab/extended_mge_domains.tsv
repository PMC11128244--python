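# Extended-library domain ids (CDD / TIGRFAM / SMART / PGAP namespaces)
# used for the secondary manual-style MGE screen. Best-effort list; the
# exact set used for any given study is rarely published.
# columns: domain_id
domain_id
cd00184
cd01025
cd03768
TIGR02224
TIGR02249
TIGR02686
TIGR03454
smart00400
smart00833
NF033520
NF033550
PGAP01368
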