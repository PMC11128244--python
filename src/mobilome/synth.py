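"""Synthetic annotated circular-element cohorts with planted structure.

The generator emulates the statistical shape of a contaminated-subsurface
meta-mobilome: a bimodal (log-normal mixture) element-length distribution
with modes near 3 kb and 70 kb, the low-contamination stratum skewed
toward the small mode; stratum-dependent planting of heavy-metal-
resistance-gene (HMRG) clusters at consecutive ORFs; conjugation modules;
per-stratum host-phylum mixtures with imperfect gene-level annotation
fidelity; and external-tool evidence (viral sorter categories, plasmid-DB
hits, CRISPR spacer matches, k-mer host calls) consistent with each
element's true class.  A ground-truth manifest records every planted
feature so downstream recovery is testable.

Everything is driven by one :func:`numpy.random.default_rng` stream, so a
fixed config + seed reproduces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import write_annotation_table, write_evidence_table, write_fasta
from .model import CircularElement, ClassLabel, EvidenceBundle, GeneFeature, Vocabulary

#: HMRG gene names observed to co-occur in planted clusters; cluster COGs
#: are drawn uniformly without replacement from this pool.
COOCCURRING_HMRG_GENES = (
    "merR", "chrB1", "chrA", "copZ", "merA", "arsR",
    "cusA", "cusF", "pcoB", "czcD", "zntA",
)

PHYLUM_CLASSES = {
    "Proteobacteria": ("Gammaproteobacteria", "Betaproteobacteria", "Alphaproteobacteria"),
    "Bacteroidetes": ("Bacteroidia", "Chitinophagia"),
    "Firmicutes": ("Bacilli", "Clostridia"),
    "Actinobacteria": ("Actinomycetia",),
    "Acidobacteria": ("Acidobacteriia",),
    "Caldiserica": ("Caldisericia",),
}

# class weights within Proteobacteria differ by stratum: contaminated sites
# are dominated by Gamma/Betaproteobacteria.
_PROTEO_CLASS_W = {
    "high_U": (0.45, 0.40, 0.15),
    "low_U": (0.20, 0.20, 0.60),
}

_BACKGROUND_PRODUCTS = (
    "hypothetical protein",
    "ABC transporter permease",
    "response regulator",
    "two-component sensor histidine kinase",
    "acyl-CoA dehydrogenase",
    "MFS transporter",
    "aminotransferase class I",
    "TonB-dependent receptor",
    "short-chain dehydrogenase",
    "GNAT family N-acetyltransferase",
)

_VIRAL_PRODUCTS = (
    "major capsid protein",
    "terminase large subunit",
    "portal protein",
    "tail fiber protein",
    "baseplate assembly protein",
    "holin",
    "endolysin",
    "phage integrase",
    "DNA polymerase",
    "tape measure protein",
)

_AMG_PRODUCTS = (
    "glutamine synthetase",
    "thioredoxin",
    "SAM-dependent methyltransferase",
    "cobalamin biosynthesis protein",
    "glycosyltransferase family 2 protein",
)

_ORGANELLE_PRODUCTS = (
    "chloroplast envelope membrane protein",
    "mitochondrial ribosomal protein S7",
    "photosystem II protein D1",
    "plastid ATP synthase subunit beta",
)

_GENUS_BY_PHYLUM = {
    "Proteobacteria": ("Rhodanobacter", "Pseudomonas", "Burkholderia", "Sphingobium"),
    "Bacteroidetes": ("Flavobacterium", "Chryseobacterium"),
    "Firmicutes": ("Bacillus", "Clostridium"),
    "Actinobacteria": ("Mycobacterium", "Streptomyces"),
    "Acidobacteria": ("Acidobacterium",),
    "Caldiserica": ("Caldisericum",),
}


def _default_weights() -> dict[str, tuple[float, float]]:
    # (w_small, w_large) per stratum
    return {"high_U": (0.5, 0.5), "low_U": (0.8, 0.2)}


def _default_hmrg_rate() -> dict[str, float]:
    return {"high_U": 0.10, "low_U": 0.02}


def _default_host_mixture() -> dict[str, dict[str, float]]:
    return {
        "high_U": {
            "Proteobacteria": 0.70, "Bacteroidetes": 0.10, "Firmicutes": 0.08,
            "Actinobacteria": 0.07, "Acidobacteria": 0.05,
        },
        "low_U": {
            "Proteobacteria": 0.35, "Bacteroidetes": 0.20, "Firmicutes": 0.15,
            "Actinobacteria": 0.15, "Acidobacteria": 0.10, "Caldiserica": 0.05,
        },
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-mobilome generator (see module docstring)."""

    seed: int = 0
    n_high: int = 338
    n_low: int = 1277
    mode_small_bp: float = 3000.0
    mode_large_bp: float = 70000.0
    length_shape: float = 0.5
    length_weights: dict[str, tuple[float, float]] = field(default_factory=_default_weights)
    min_length_bp: int = 1001
    gene_pitch_bp: float = 1000.0
    p_viral: float = 0.07
    p_viral_decoy: float = 0.02
    p_plasmid_hit: float = 0.015
    p_mge_pfam: float = 0.30
    p_mge_extended: float = 0.08
    hmrg_cluster_rate: dict[str, float] = field(default_factory=_default_hmrg_rate)
    cluster_poisson_mean: float = 3.0
    p_conj: float = 0.25
    conj_size_threshold_bp: int = 20000
    p_conj_hmrg: Optional[float] = 0.9
    p_viral_hmrg_amg: float = 0.01
    host_mixture: dict[str, dict[str, float]] = field(default_factory=_default_host_mixture)
    annotation_fidelity: float = 0.7
    p_unannotated_tax: float = 0.2
    php_accuracy: float = 0.8
    p_false_positive: float = 0.057
    emit_sequences: bool = False

    def validate(self) -> None:
        probs = [
            self.p_viral, self.p_viral_decoy, self.p_plasmid_hit, self.p_mge_pfam,
            self.p_mge_extended, self.p_conj, self.annotation_fidelity,
            self.p_unannotated_tax, self.php_accuracy, self.p_false_positive,
            self.p_viral_hmrg_amg,
        ] + list(self.hmrg_cluster_rate.values())
        if self.p_conj_hmrg is not None:
            probs.append(self.p_conj_hmrg)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_high < 0 or self.n_low < 0:
            raise ValueError("element counts must be >= 0")
        for stratum, n in (("high_U", self.n_high), ("low_U", self.n_low)):
            w = self.length_weights[stratum]
            if n > 0 and sum(w) == 0:
                raise ValueError(f"zero-weight length mixture in stratum {stratum}")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"length mixture weights must sum to 1 in {stratum}")
            mix = self.host_mixture[stratum]
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"host mixture must sum to 1 in {stratum}")

    def mixture_mean_bp(self, stratum: str) -> float:
        """Closed-form mean of the configured length mixture."""
        w_small, w_large = self.length_weights[stratum]
        scale = math.exp(self.length_shape**2 / 2)
        return (w_small * self.mode_small_bp + w_large * self.mode_large_bp) * scale


def null_config(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``config`` with no planted stratum effect.

    HMRG cluster rate, host mixture, and length mixture take the
    low-stratum values in both strata; idempotent.
    """
    config.validate()
    c = dataclasses.replace(config)
    c.hmrg_cluster_rate = {s: config.hmrg_cluster_rate["low_U"] for s in ("high_U", "low_U")}
    c.host_mixture = {s: dict(config.host_mixture["low_U"]) for s in ("high_U", "low_U")}
    c.length_weights = {s: tuple(config.length_weights["low_U"]) for s in ("high_U", "low_U")}
    return c


def power_config(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``config`` isolating the HMRG-rate contrast.

    Length and host mixtures are equalized across strata (high-stratum
    values in both) while the per-stratum HMRG cluster rates are kept, so
    the planted rate ratio is also the per-CDS rate ratio.
    """
    config.validate()
    c = dataclasses.replace(config)
    c.host_mixture = {s: dict(config.host_mixture["high_U"]) for s in ("high_U", "low_U")}
    c.length_weights = {s: tuple(config.length_weights["high_U"]) for s in ("high_U", "low_U")}
    return c


@dataclass
class ElementTruth:
    element_id: str
    true_class: str
    true_host_phylum: Optional[str]
    true_host_class: Optional[str]
    planted_hmrg_positions: list[int]
    planted_hmrg_cogs: list[str]
    planted_conj: bool
    removal_reason: Optional[str] = None  # organelle / tandem_repeat_artifact


@dataclass
class GroundTruth:
    elements: dict[str, ElementTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {eid: dataclasses.asdict(t) for eid, t in sorted(self.elements.items())},
            indent=1,
        )


class _Simulator:
    def __init__(self, config: GeneratorConfig, vocab: Vocabulary):
        config.validate()
        self.cfg = config
        self.vocab = vocab
        self.rng = np.random.default_rng(config.seed)
        name_to_cog = {name: cog for cog, name in vocab.cog_gene_names.items()}
        self.cluster_pool = [name_to_cog[g] for g in COOCCURRING_HMRG_GENES]
        self.conj_pool = sorted(vocab.conj_cogs)
        self.neutral_pool = [f"COG9{i:03d}" for i in range(200)]
        self.mge_pfams = sorted(vocab.mge_pfams)
        self.repl_pfams = sorted(vocab.replication_pfams)
        self.ext_domains = sorted(vocab.extended_mge_domains)
        self.hmrg_name = dict(vocab.cog_gene_names)

    # -- small draws ------------------------------------------------------
    def _choice(self, seq, p=None):
        return seq[self.rng.choice(len(seq), p=p)]

    def _draw_length(self, stratum: str) -> int:
        w_small, _ = self.cfg.length_weights[stratum]
        mode = self.cfg.mode_small_bp if self.rng.random() < w_small else self.cfg.mode_large_bp
        length = int(round(self.rng.lognormal(math.log(mode), self.cfg.length_shape)))
        return max(length, self.cfg.min_length_bp)

    def _draw_host(self, stratum: str) -> tuple[str, str]:
        mix = self.cfg.host_mixture[stratum]
        phyla = sorted(mix)
        phylum = self._choice(phyla, p=np.array([mix[p] for p in phyla]))
        classes = PHYLUM_CLASSES[phylum]
        if phylum == "Proteobacteria":
            klass = self._choice(classes, p=np.array(_PROTEO_CLASS_W[stratum]))
        else:
            klass = self._choice(classes)
        return phylum, klass

    def _gene_taxonomy(self, host: tuple[str, str]) -> Optional[tuple[str, str]]:
        if self.rng.random() < self.cfg.p_unannotated_tax:
            return None
        if self.rng.random() < self.cfg.annotation_fidelity:
            return host
        others = [p for p in PHYLUM_CLASSES if p != host[0]]
        phylum = self._choice(others)
        return phylum, self._choice(PHYLUM_CLASSES[phylum])

    def _gene_coords(self, length: int, n_genes: int) -> list[tuple[int, int]]:
        if n_genes == 1:
            return [(1, length)]
        starts = np.sort(self.rng.choice(length, size=n_genes, replace=False)) + 1
        coords = []
        for i in range(n_genes):
            start = int(starts[i])
            if i + 1 < n_genes:
                end = int(starts[i + 1]) - 1
            else:
                end = int(starts[0]) - 1 + length  # spans the origin
            coords.append((start, max(end, start)))
        return coords

    def _random_sequence(self, length: int) -> str:
        return "".join(np.array(list("ACGT"))[self.rng.integers(0, 4, size=length)])

    def _repeat_sequence(self, length: int) -> tuple[str, int]:
        k = int(self.rng.integers(2, 6))
        unit_len = max(length // k, 50)
        length = unit_len * k
        unit = self._random_sequence(unit_len)
        seq = list(unit * k)
        # ~1% per-base divergence between copies, well above the 95%
        # identity screen threshold
        n_mut = self.rng.binomial(len(seq), 0.01)
        for pos in self.rng.choice(len(seq), size=n_mut, replace=False):
            seq[pos] = self._choice("ACGT")
        return "".join(seq), length

    # -- element assembly -------------------------------------------------
    def build(self) -> tuple[list[CircularElement], dict[str, EvidenceBundle], GroundTruth]:
        cfg = self.cfg
        elements: list[CircularElement] = []
        evidence: dict[str, EvidenceBundle] = {}
        truth = GroundTruth()
        plan = [("high_U", i, f"H{i + 1:04d}") for i in range(cfg.n_high)]
        plan += [("low_U", i, f"L{i + 1:04d}") for i in range(cfg.n_low)]
        for stratum, _, eid in plan:
            el, ev, tr = self._build_element(eid, stratum)
            elements.append(el)
            evidence[eid] = ev
            truth.elements[eid] = tr
        return elements, evidence, truth

    def _build_element(self, eid: str, stratum: str):
        cfg, rng = self.cfg, self.rng
        length = self._draw_length(stratum)
        sequence = None
        removal_reason = None

        # decide the true class first; evidence and annotations follow it
        u = rng.random()
        if u < cfg.p_false_positive:
            true_class = ClassLabel.REMOVED_FALSE_POSITIVE
            if cfg.emit_sequences and rng.random() < 0.5:
                removal_reason = "tandem_repeat_artifact"
                sequence, length = self._repeat_sequence(length)
            else:
                removal_reason = "organelle"
        elif u < cfg.p_false_positive + cfg.p_viral:
            true_class = ClassLabel.VIRAL
        elif u < cfg.p_false_positive + cfg.p_viral + cfg.p_viral_decoy:
            true_class = ClassLabel.CRYPTIC  # decoy: low-confidence viral category only
        else:
            v = rng.random()
            if v < cfg.p_plasmid_hit:
                true_class = ClassLabel.PLASMID
            elif v < cfg.p_plasmid_hit + cfg.p_mge_pfam:
                true_class = ClassLabel.UNCLASSIFIED_MGE
            elif v < cfg.p_plasmid_hit + cfg.p_mge_pfam + cfg.p_mge_extended:
                true_class = ClassLabel.UNCLASSIFIED_MGE
                removal_reason = None
            else:
                true_class = ClassLabel.CRYPTIC
        mge_tier_extended = (
            true_class is ClassLabel.UNCLASSIFIED_MGE
            and v >= cfg.p_plasmid_hit + cfg.p_mge_pfam
        ) if true_class is ClassLabel.UNCLASSIFIED_MGE else False

        host = self._draw_host(stratum)
        n_genes = max(1, int(rng.poisson(length / cfg.gene_pitch_bp)))
        coords = self._gene_coords(length, n_genes)

        organelle = true_class is ClassLabel.REMOVED_FALSE_POSITIVE and removal_reason == "organelle"
        viral = true_class is ClassLabel.VIRAL

        # plant HMRG cluster (non-viral, non-false-positive elements)
        hmrg_positions: list[int] = []
        hmrg_cogs: list[str] = []
        if not viral and true_class is not ClassLabel.REMOVED_FALSE_POSITIVE:
            if rng.random() < cfg.hmrg_cluster_rate[stratum]:
                size = 1 + int(rng.poisson(cfg.cluster_poisson_mean))
                size = min(size, n_genes, len(self.cluster_pool))
                start = int(rng.integers(n_genes))
                hmrg_positions = [(start + i) % n_genes for i in range(size)]
                picked = rng.choice(len(self.cluster_pool), size=size, replace=False)
                hmrg_cogs = [self.cluster_pool[i] for i in picked]
        elif viral and rng.random() < cfg.p_viral_hmrg_amg:
            # a rare metal-resistance auxiliary metabolic gene on a phage
            hmrg_positions = [int(rng.integers(n_genes))]
            hmrg_cogs = ["COG2310"]  # terD

        # plant conjugation module
        planted_conj = False
        conj_assignment: dict[int, list[str]] = {}
        if not viral and true_class is not ClassLabel.REMOVED_FALSE_POSITIVE:
            if hmrg_positions and cfg.p_conj_hmrg is not None:
                p_conj = cfg.p_conj_hmrg
            elif length > cfg.conj_size_threshold_bp:
                p_conj = cfg.p_conj
            else:
                p_conj = 0.0
            if rng.random() < p_conj:
                planted_conj = True
                k = int(rng.integers(5, 11))
                cogs = [self.conj_pool[i] for i in rng.choice(len(self.conj_pool), size=k, replace=False)]
                avail = [i for i in range(n_genes) if i not in hmrg_positions] or list(range(n_genes))
                targets = rng.permutation(avail)
                for j, cog in enumerate(cogs):
                    conj_assignment.setdefault(int(targets[j % len(targets)]), []).append(cog)

        # MGE-domain carriers
        pfam_gene = ext_gene = None
        pfam_choice = ext_choice = None
        if true_class is ClassLabel.UNCLASSIFIED_MGE:
            if mge_tier_extended:
                ext_gene = int(rng.integers(n_genes))
                ext_choice = self._choice(self.ext_domains)
            else:
                pfam_gene = int(rng.integers(n_genes))
                pfam_choice = self._choice(self.mge_pfams)
        elif true_class is ClassLabel.PLASMID and rng.random() < 0.6:
            # plasmids frequently carry a replication Pfam too
            pfam_gene = int(rng.integers(n_genes))
            pfam_choice = self._choice(self.repl_pfams)

        genes = []
        for i in range(n_genes):
            start, end = coords[i]
            cog_ids: set[str] = set()
            pfam_ids: set[str] = set()
            domain_ids: set[str] = set()
            taxonomy = None
            product = ""
            if organelle:
                if rng.random() < 0.8:
                    product = self._choice(_ORGANELLE_PRODUCTS)
                    taxonomy = ("Streptophyta", "Magnoliopsida")
                else:
                    product = self._choice(_BACKGROUND_PRODUCTS)
            elif i in hmrg_positions:
                cog = hmrg_cogs[hmrg_positions.index(i)]
                cog_ids.add(cog)
                # tiny elements may host the conjugation module on the same
                # genes as the resistance cluster
                cog_ids.update(conj_assignment.get(i, []))
                product = f"{self.hmrg_name.get(cog, cog)} family metal resistance protein"
                taxonomy = self._gene_taxonomy(host)
            elif viral:
                r = rng.random()
                if r < 0.70:
                    product = self._choice(_VIRAL_PRODUCTS)
                elif r < 0.85:
                    product = self._choice(_AMG_PRODUCTS)
                    cog_ids.add(self._choice(self.neutral_pool))
                else:
                    product = "hypothetical protein"
                taxonomy = self._gene_taxonomy(host)
            else:
                if i in conj_assignment:
                    for cog in conj_assignment[i]:
                        cog_ids.add(cog)
                    product = "type IV secretion system protein"
                elif rng.random() < 0.6:
                    cog_ids.add(self._choice(self.neutral_pool))
                    product = self._choice(_BACKGROUND_PRODUCTS)
                else:
                    product = "hypothetical protein" if rng.random() < 0.5 else ""
                taxonomy = self._gene_taxonomy(host)
            if i == pfam_gene and pfam_choice is not None:
                pfam_ids.add(pfam_choice)
            if i == ext_gene and ext_choice is not None:
                domain_ids.add(ext_choice)
            genes.append(GeneFeature(
                gene_id=f"{eid}_g{i:03d}",
                orf_index=i,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                cog_ids=frozenset(cog_ids),
                pfam_ids=frozenset(pfam_ids),
                domain_ids=frozenset(domain_ids),
                taxonomy=taxonomy,
                product=product,
            ))

        if cfg.emit_sequences and sequence is None:
            sequence = self._random_sequence(length)

        element = CircularElement(
            element_id=eid, sample_id=f"S_{stratum}", stratum=stratum,
            length_bp=length, genes=genes, sequence=sequence,
        )

        # -- evidence ------------------------------------------------------
        category = None
        plsdb_hit = None
        crispr: list[tuple[str, int]] = []
        php = None
        lifestyle = None
        if viral:
            category = int(self._choice([1, 2, 4, 5]))
            lifestyle = "temperate" if rng.random() < 0.45 else "virulent"
            if rng.random() < cfg.php_accuracy:
                php = host[0]
            else:
                php = self._choice([p for p in PHYLUM_CLASSES if p != host[0]])
            if rng.random() < 0.3:
                for _ in range(int(rng.integers(1, 4))):
                    genus = self._choice(_GENUS_BY_PHYLUM[host[0]])
                    crispr.append((genus, int(rng.integers(0, 4))))
        elif true_class is ClassLabel.CRYPTIC and u >= cfg.p_false_positive + cfg.p_viral \
                and u < cfg.p_false_positive + cfg.p_viral + cfg.p_viral_decoy:
            category = int(self._choice([3, 6]))  # low-confidence decoy
        if true_class is ClassLabel.PLASMID:
            meta_host = host[0] if rng.random() < 0.9 else self._choice(
                [p for p in PHYLUM_CLASSES if p != host[0]])
            genus = self._choice(_GENUS_BY_PHYLUM[meta_host])
            plsdb_hit = (
                f"NZ_CP{int(rng.integers(10_000, 99_999)):05d}",
                round(float(rng.uniform(0.0, 0.1)), 4),
                round(float(rng.uniform(0.0, 0.1)), 6),
                f"{genus} ({meta_host})",
            )
        bundle = EvidenceBundle(
            element_id=eid, virsorter_category=category, plsdb_hit=plsdb_hit,
            crispr_hits=crispr, php_phylum=php, lifestyle=lifestyle,
        )

        tr = ElementTruth(
            element_id=eid,
            true_class=true_class.value,
            true_host_phylum=None if organelle else host[0],
            true_host_class=None if organelle else host[1],
            planted_hmrg_positions=list(hmrg_positions),
            planted_hmrg_cogs=list(hmrg_cogs),
            planted_conj=planted_conj,
            removal_reason=removal_reason,
        )
        return element, bundle, tr


def simulate(
    config: GeneratorConfig, vocab: Vocabulary
) -> tuple[list[CircularElement], dict[str, EvidenceBundle], GroundTruth]:
    """Generate a synthetic cohort; deterministic for a fixed config+seed."""
    return _Simulator(config, vocab).build()


def write_outputs(
    elements, evidence, truth: GroundTruth, outdir: str | Path,
    emit_fasta: bool = False,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_annotation_table(elements, outdir / "annotations.tsv")
    write_evidence_table(
        [evidence[el.element_id] for el in elements], outdir / "evidence.tsv"
    )
    (outdir / "truth.json").write_text(truth.to_json(), encoding="utf-8")
    if emit_fasta and any(el.sequence is not None for el in elements):
        write_fasta([el for el in elements if el.sequence is not None],
                    outdir / "elements.fasta")
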