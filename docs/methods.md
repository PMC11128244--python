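# Methods

## Data model

A *circular element* is a circularized DNA sequence with an ordered list
of CDS features. Coordinates are 1-based inclusive on the circular
contig; a gene spanning the origin is written with `end > length_bp` and
interpreted modulo the element length. Ordinal gene positions
(`orf_index`, 0..n−1) drive all neighborhood statistics; topology is
always circular. Each element carries a contamination-stratum label
(`high_U` / `low_U`). The stratum split is an upstream decision — a
helper maps a groundwater uranium concentration to a stratum at the
0.126 μM drinking-water limit — and the pipeline treats it as given.

External-tool results arrive as an *evidence bundle* per element: a viral
sorter category (1–6), a plasmid-database mash hit (distance, p-value,
host metadata), CRISPR-spacer hits with mismatch counts, a k-mer host
phylum, and a phage lifestyle call. These are consumed, never recomputed.

## Screening

*Organelle screen.* An element is removed when ≥ 50% (inclusive) of its
annotated genes — those carrying a product string or a taxonomy — match
an organelle keyword (mitochondri/chloroplast/plastid/… or a eukaryotic
lineage token) by case-insensitive substring. The denominator excludes
fully unannotated genes so sparse annotation does not shield an obvious
organelle fragment, and an element with no annotation at all is never
flagged.

*Tandem-repeat screen.* A circular sequence that is k ≥ 2 whole tandem
copies of one unit is an assembly artifact. We test every divisor k of
the length with unit ≥ 50 bp and flag the element when every copy matches
the first copy at ≥ 95% identity. Periodicity is rotation-invariant on a
circle, so no rotation search is needed. Absent sequence means the screen
cannot run; the element passes with a warning.

*Dereplication* is greedy and longest-first within one stratum. Exact
duplicates are found in O(n log n) via a canonical form: the
lexicographically least rotation (Booth's algorithm) of
min(sequence, reverse complement). Near-duplicates join a representative
when the shorter sequence aligns inside the doubled longer one (edlib
infix alignment, both strands) at ≥ 99% identity; doubling the target
makes the search rotation-invariant, and the infix mode aligns the whole
shorter sequence, satisfying the ≥ 90% coverage-of-shorter contract by
construction. Without sequences the fallback is exact equality of the
rotation/orientation-invariant ordered COG/Pfam fingerprint **plus the
element length** — two sparsely annotated 3-kb circles with identical
(often empty) gene fingerprints but different lengths are distinct
replicons, and omitting the length collapsed ~10% of small synthetic
elements in early testing. Thresholds (0.5 organelle fraction, 0.95
repeat identity, 0.99/0.90 dereplication) are exposed in the run config;
they are documented defaults chosen to be conservative, not fitted to any
dataset.

## Classification cascade

Tier order mirrors the sequential workflow that produced the evidence:
(1) viral iff the sorter category is in {1,2,4,5} — low-confidence
categories 3 and 6 are ignored entirely; (2) plasmid iff a
plasmid-database hit has mash p ≤ 0.1 **and** distance ≤ 0.1 (inclusive,
since these are stated as search parameters); (3) unclassified MGE iff
any gene carries an MGE-related Pfam; (4) unclassified MGE iff any gene
carries an extended-library (CDD/TIGRFAM/SMART/PGAP) MGE domain;
(5) cryptic otherwise. Exactly one tier fires; the viral tier outranks
the plasmid tier because the plasmid comparison was only ever run on
non-viral elements. A `plasmid_replication_domain` flag records whether
any matched Pfam belongs to the plasmid-replication subset.

The packaged vocabularies (HMRG COGs with their metal sets, ARG COGs,
conjugal-transfer COGs, MGE Pfams with the replication subset, extended
domain ids, viral-function and organelle keyword lists) are best-effort
curated transcriptions from the public COG/Pfam databases; a few gene
names (cusF, chrB1, tehB) lack a canonical COG and carry best-effort
ids. Users can override any file via a vocabulary directory. The
extended-domain list in particular is flagged as a best-effort
transcription: published studies rarely enumerate the exact keyword set
used for manual domain screens, so tier-4 behavior depends on the
shipped list.

## Host assignment

Gene-level (phylum, class) annotations are tallied per element at the
requested level; the modal taxon is assigned iff its count strictly
exceeds half of the denominator. The default denominator is **all** CDS
(unannotated genes count against the majority) — the conservative
reading of a ">50% of CDS" rule and the one consistent with high
unassigned rates in sparsely annotated elements; `denominator=annotated`
is available as a switch. Ties at exactly one half are unassigned.
Phylum and class votes are computed independently. Viral hosts come from
the k-mer predictor's phylum column; CRISPR hits filtered to ≤ 1
mismatch give genus-level refinements, deduplicated in first-seen order.
Where an element has a plasmid-database hit, a report column records
whether the vote agrees with the hit's host metadata (phylum-level,
string-normalized containment).

## Resistance statistics

Gene screening emits one hit per (gene, matching COG); a gene with two
HMRG COGs yields two hits, and hit-level counting feeds all densities
("absolute gene counts"). Densities are per Mbp of element sequence
(denominator: total element bp, not annotated bp) and per CDS. Per-COG
enrichment uses the 2×2 table (count, total CDS − count) in the two
strata, the minimum-likelihood two-sided Fisher exact test
(scipy.stats.fisher_exact), and BH step-up q-values across all COGs of
the category — rows are emitted for every vocabulary COG, including
0/0 rows at p = 1, so the correction is over the full curated family.
Odds ratios get a Haldane–Anscombe 0.5 correction for display only. A
conservative re-run excludes cryptic elements.

The neighborhood statistic pools all HMRG gene hits in a set and reports
the fraction with ≥ 1 *other* HMRG-bearing gene at circular ordinal
distance ≤ 4 (min of clockwise/counter-clockwise); the wrap can be
disabled (`--linear`) for sensitivity analysis, and a per-element
averaging mode exists because pooled counting is a choice, not a law.
Two HMRG COGs on one gene never make that gene self-adjacent. An empty
HMRG set returns "undefined" (None), distinct from 0.

The conjugation analysis is element-level on non-viral elements only:
a 2×2 table of (carries ≥ 1 conjugal-transfer COG) × (carries ≥ 1 HMRG),
Fisher-tested, plus the fraction of HMRG gene hits residing on
conjugative elements. AMG calling on viral elements reports genes that
carry a functional annotation (non-empty, non-"hypothetical" product or
a COG) and match no viral replication/structure/function keyword;
HMRG-category AMGs are flagged with their metal sets. Size statistics
use strict thresholds (> 20 kb, > 100 kb) and Welch's two-sided t-test
with the Welch–Satterthwaite df.

## Synthetic cohorts

The generator emulates, per stratum: element lengths from a two-component
log-normal mixture (location parameters ln 3000 and ln 70000, shape 0.5;
weights 0.5/0.5 high, 0.8/0.2 low; minimum 1001 bp), gene counts at
~1 gene/kb (Poisson, ≥ 1), gene coordinates partitioning the circle with
the last gene spanning the origin, and a true class drawn as: screening
decoy 5.7%, viral 7% (categories from {1,2,4,5}; 2% additional decoys
with categories {3,6}), then plasmid 1.5% / Pfam-tier MGE 30% /
extended-tier MGE 8% / cryptic among non-viral. Default cohort sizes are
338 high / 1277 low. HMRG clusters are planted on non-viral elements at
rate 0.10 (high) / 0.02 (low), occupy consecutive ORFs, have size
1 + Poisson(3) capped by the gene count, and draw COGs uniformly without
replacement from the 11-gene co-occurring pool (merR, chrB1, chrA, copZ,
merA, arsR, cusA, cusF, pcoB, czcD, zntA) — uniform weighting maximizes
per-COG detection power for a fixed planted-gene budget. Conjugation
modules (5–10 distinct conjugal COGs) go on elements > 20 kb with
probability 0.25, and on HMRG-cluster elements with probability 0.9,
mirroring the strong observed linkage between resistance cargo and
self-transmissibility; setting that coupling to None restores
independence for null testing. Hosts come from per-stratum phylum
mixtures (high skewed 70% to Proteobacteria, class weights skewed to
Gamma/Beta in the high stratum); each gene's taxonomy equals the true
host with fidelity 0.7, is absent with probability 0.2, and is otherwise
a random other lineage. Viral elements get 70% structural products, 15%
functional (AMG-candidate) products, 15% hypotheticals, a k-mer host
call correct with probability 0.8, and occasionally CRISPR hits;
1% carry a single tellurium-family HMRG as an AMG. Background genes draw
from a neutral COG pool disjoint from every curated list, so planted
signal is unambiguous. All draws come from one `default_rng(seed)`
stream: identical config + seed reproduces files byte-for-byte, and the
ground-truth manifest records planted classes, hosts, HMRG positions and
COGs, and conjugation flags exactly.

What the generator does **not** emulate: nucleotide-level evolution (no
sequence homology between related elements), assembly coverage effects,
annotation databases' real error structure, correlated gene order beyond
the planted clusters, or the mash/viral-sorter decision internals.
Passing recovery tests therefore demonstrates that the analysis logic is
correct and calibrated on data with the assumed statistical shape — not
that the upstream tools are accurate on real sequences.

## Calibration harnesses and their design

`null_config` copies the low-stratum HMRG rate, host mixture, and length
mixture into both strata (idempotent), so any enrichment discovery is a
false discovery; over 20 seeds at 400+400 elements the observed
discovery fraction is 0 — BH control holds with large margin.

`power_config` keeps the 0.10/0.02 cluster-rate contrast but equalizes
the length and host mixtures across strata (high-stratum values in
both). This is deliberate: with unequal length mixtures, the low
stratum's smaller elements shrink its CDS denominator, and the realized
per-CDS rate ratio collapses from 5× to ~2.2×, so a per-COG power
criterion would measure the mixture asymmetry rather than the detector.
Even with equalized mixtures, the arithmetic caps power: ~400×0.10×3.2 ≈
110 planted genes in the high stratum spread over 11 pool COGs give
expected per-COG counts near 10 vs 2, whose Fisher p-values (~0.01–0.09)
straddle the BH q<0.05 boundary at m=20 tests; the measured 20-seed
average fraction of planted COGs reaching q<0.05 is ≈ 0.39. This is a
property of the prescribed rates, cohort size, cluster-size law, and
pool — not a numerical defect — and the corresponding acceptance test is
left failing rather than quietly re-parameterized; the category-level
contrast (all HMRGs pooled) is detected in essentially every seed.

Density-ratio recovery compares the pipeline-measured per-Mbp ratio
(pooled over 20 seeds of 400+400 default cohorts, after screening and
dereplication) with a closed-form expectation that integrates the
cluster-size law min(1 + Pois(3), n_genes, 11) over the gene-count law
max(1, Pois(L/1000)) and the length mixture by quantile quadrature. The
expectation was verified against a 60 000-element simulation (agreement
to 0.3%); at the calibration scale the pooled estimator's sampling sd is
~8%, so the 15% acceptance band is roughly a 2σ check.

## Numerical choices and degenerate inputs

Fisher on the all-zero table returns p = 1 with a warning. Welch's test
requires n ≥ 2 per sample and nonzero pooled variance (identical samples
with variance give t = 0, p = 1; two constant samples are an error).
BH requires p ∈ (0,1] and preserves input order. The vote winner is
deterministic under count ties (lexicographic). Dereplication output
order is length-descending then id, making representatives and reports
order-independent. Pipeline summaries embed the resolved configuration
and SHA-256 checksums of the vocabulary files; identical config + inputs
give byte-identical JSON.

## Known limitations

- The curated COG/Pfam lists are best-effort transcriptions; a handful of
  gene-name→COG mappings have no canonical counterpart in the public COG
  release and the extended-domain list is inherently incomplete.
- Dereplication without sequences degrades to an annotation fingerprint
  and cannot detect diverged duplicates.
- Real dereplication criteria for published cohorts are rarely stated;
  whether identity-based clustering reproduces any given study's manual
  dereplication is unknowable, so exact replication of historical counts
  (e.g. a specific number of removed assemblies) is out of scope.
- The per-COG enrichment power at the default planted rates is ~0.4 (see
  above); detecting individual-gene enrichment at q<0.05 with these
  cohort sizes requires either stronger planting or larger cohorts.
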