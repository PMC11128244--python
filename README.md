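# mobilome

Classification, host assignment, and heavy-metal-resistance statistics for
populations of circularized mobile genetic elements (MGEs) recovered from
environmental metagenomes.

## The problem

Metagenome assembly graphs of contaminated subsurface environments yield
thousands of circularized DNA elements — plasmids, phage genomes,
integrative/conjugative elements, and "cryptic" circles with no
recognizable MGE machinery. Comparing the element populations of
high-contamination versus low-contamination strata (split at a groundwater
uranium concentration of 0.126 μM) asks a chain of questions this package
answers as a single reproducible pipeline:

1. **Screening** — remove artifact "elements" (partial organellar genomes,
   tandem-repeat regions that circularized inappropriately) and collapse
   near-identical replicons within each stratum (rotation- and
   strand-invariant identity ≥ 99%).
2. **Classification** — a four-tier cascade: *viral* (confident viral-sorter
   category ∈ {1,2,4,5}), else *plasmid* (mash hit to a plasmid database
   with *P* ≤ 0.1 and distance ≤ 0.1), else *unclassified MGE* (MGE-related
   Pfam, or an extended CDD/TIGRFAM/SMART/PGAP domain), else *cryptic*.
3. **Host assignment** — for non-viral elements, a strict majority vote over
   gene-level taxonomy (taxon assigned iff > 50% of CDS agree); viral hosts
   from a k-mer predictor column, refined by CRISPR-spacer hits filtered to
   ≤ 1 mismatch.
4. **Resistance statistics** — heavy-metal-resistance gene (HMRG) densities
   per Mbp and per CDS; per-COG enrichment between strata by two-tailed
   Fisher exact tests with Benjamini–Hochberg FDR; the probability that an
   HMRG lies within ±4 ORFs of another HMRG on the circle; HMRG
   co-occurrence matrices; the element-level association between HMRG
   carriage and conjugal-transfer machinery; auxiliary metabolic gene (AMG)
   calling on viral elements.

For a COG *g* with hit counts \(a\) (high stratum) and \(c\) (low stratum)
out of \(N_h\) and \(N_l\) total CDS, enrichment is tested on the table
\(\begin{smallmatrix}a & N_h-a\\ c & N_l-c\end{smallmatrix}\) with the
minimum-likelihood two-sided Fisher convention, and q-values are the BH
step-up \(q_{(i)} = \min_{j\ge i} p_{(j)} m / j\).

Because the real cohorts require external tools (assembler, viral sorter,
mash, eggNOG-mapper), the package ships a **synthetic-mobilome generator**
that emulates the statistical structure of such a cohort — bimodal
log-normal length mixture (modes ≈ 3 kb and 70 kb, the low stratum skewed
4:1 toward the small mode), stratum-dependent planting of HMRG clusters at
consecutive ORFs, conjugation modules, per-stratum host mixtures with
imperfect annotation fidelity, and class-consistent external evidence —
together with a ground-truth manifest, so every stage is testable without
downloads.

## Worked example

```bash
python analysis/01_simulate_cohort.py      # synthetic cohort, 338 + 1277 elements
python analysis/02_screen_classify.py      # screening + four-tier classification
python analysis/03_host_prediction.py      # majority-vote + CRISPR host calls
python analysis/04_resistance_analysis.py  # densities, enrichment, adjacency, ...
python analysis/05_calibration.py          # 20-seed null/power/recovery harnesses
```

Output of step 04 on the default cohort (seed 1):

```
high_U: 12.3 HMRGs/Mbp (1.2% of CDS)
low_U: 4.2 HMRGs/Mbp (0.4% of CDS)
adjacency probability (+/-4 ORFs): {'high_U': 0.955, 'low_U': 0.84}
HMRG on conjugative elements: 88.2% (Fisher p = 2.52e-63)
significant HMRG COGs at q<0.05: 6 | ARG: 0
length contrast: Welch t = 7.36, p = 9.49e-13
```

Reading: the high-contamination stratum carries a ~3× higher HMRG density;
planted resistance clusters make an HMRG almost always sit within four ORFs
of another one; 88% of HMRG gene hits ride on elements that also encode a
conjugal-transfer module (the planted coupling is 0.9), and six individual
resistance genes reach q < 0.05 while no antibiotic-resistance gene does.
The same library surfaces are scriptable through a CLI
(`mobilome simulate|screen|classify|host|analyze|run`).

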