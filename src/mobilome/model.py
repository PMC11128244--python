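"""Domain types for circularized mobile-genetic-element (MGE) analysis.

The central objects are :class:`CircularElement` — one circularized DNA
element recovered from a metagenome assembly graph, with an ordered list of
:class:`GeneFeature` coding sequences — and :class:`EvidenceBundle`, the
per-element outputs of external classifiers (viral sorter category,
plasmid-database hit, CRISPR-spacer matches, k-mer host prediction) that
this package consumes but never recomputes.

Coordinates are 1-based inclusive on the circular contig; a gene spanning
the origin is written with ``end > length_bp`` and interpreted modulo the
element length.  Topology is always circular.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class ClassLabel(str, enum.Enum):
    """Final classification of a circular element."""

    REMOVED_FALSE_POSITIVE = "removed_false_positive"
    VIRAL = "viral"
    PLASMID = "plasmid"
    UNCLASSIFIED_MGE = "unclassified_mge"
    CRYPTIC = "cryptic"


STRATA = ("high_U", "low_U")

#: Uranium concentration (uM) separating high- from low-contamination sites,
#: the US EPA drinking-water maximum contaminant level.
URANIUM_THRESHOLD_UM = 0.126


def stratum_from_uranium(u_um: float) -> str:
    """Map a groundwater uranium concentration (uM) to a contamination stratum."""
    if u_um < 0:
        raise ValueError(f"negative uranium concentration: {u_um}")
    return "high_U" if u_um > URANIUM_THRESHOLD_UM else "low_U"


@dataclass
class GeneFeature:
    """One CDS on a circular element.

    ``orf_index`` is the ordinal position around the circle (0..n-1).
    ``cog_ids``/``pfam_ids`` come from the orthology annotation;
    ``domain_ids`` from extended domain libraries (CDD/TIGRFAM/SMART/PGAP
    namespaces).  ``taxonomy`` is the (phylum, class) pair of the best
    ortholog hit, or ``None`` when unannotated.
    """

    gene_id: str
    orf_index: int
    start: int
    end: int
    strand: str
    cog_ids: frozenset[str] = frozenset()
    pfam_ids: frozenset[str] = frozenset()
    domain_ids: frozenset[str] = frozenset()
    taxonomy: Optional[tuple[str, str]] = None
    product: str = ""

    def __post_init__(self) -> None:
        if self.orf_index < 0:
            raise ValueError(f"{self.gene_id}: orf_index must be >= 0")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class CircularElement:
    """A circularized DNA element with ordered gene features."""

    element_id: str
    sample_id: str
    stratum: str
    length_bp: int
    genes: list[GeneFeature] = field(default_factory=list)
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(
                f"{self.element_id}: unknown stratum {self.stratum!r}"
            )
        if self.length_bp < 200:
            raise ValueError(f"{self.element_id}: length_bp must be >= 200")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValueError(
                f"{self.element_id}: sequence length {len(self.sequence)} "
                f"!= length_bp {self.length_bp}"
            )
        self.genes.sort(key=lambda g: g.orf_index)
        idxs = [g.orf_index for g in self.genes]
        if idxs != list(range(len(idxs))):
            raise ValueError(
                f"{self.element_id}: orf_index values must be consecutive "
                f"0..n-1, got {idxs}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class EvidenceBundle:
    """Per-element external-tool evidence.

    All fields other than ``element_id`` are optional: absence means the
    upstream tool returned nothing for this element, which is distinct
    from a zero.
    """

    element_id: str
    virsorter_category: Optional[int] = None
    plsdb_hit: Optional[tuple[str, float, float, str]] = None  # accession, mash dist, mash p, host metadata
    crispr_hits: list[tuple[str, int]] = field(default_factory=list)  # (source taxon, mismatches)
    php_phylum: Optional[str] = None
    lifestyle: Optional[str] = None

    def __post_init__(self) -> None:
        if self.virsorter_category is not None and self.virsorter_category not in range(1, 7):
            raise ValueError(
                f"{self.element_id}: virsorter_category must be in 1..6"
            )
        if self.plsdb_hit is not None:
            _, dist, pval, _ = self.plsdb_hit
            if not (0.0 <= dist <= 1.0):
                raise ValueError(f"{self.element_id}: mash_distance outside [0,1]")
            if not (0.0 <= pval <= 1.0):
                raise ValueError(f"{self.element_id}: mash_pvalue outside [0,1]")
        for taxon, mm in self.crispr_hits:
            if mm < 0:
                raise ValueError(f"{self.element_id}: negative mismatch count for {taxon}")
        if self.lifestyle is not None and self.lifestyle not in ("temperate", "virulent"):
            raise ValueError(f"{self.element_id}: unknown lifestyle {self.lifestyle!r}")


@dataclass
class Vocabulary:
    """Curated gene/domain vocabularies driving screening and classification.

    hmrg_cogs maps a COG id to the set of metal symbols the gene confers
    resistance to; cog_gene_names maps the same ids to canonical gene names
    (zntA, merA, ...).  mge_pfams are Pfam ids diagnostic of MGE replication
    or mobilization, with ``replication_pfams`` the plasmid-replication
    subset.  extended_mge_domains covers the secondary CDD/TIGRFAM/SMART/
    PGAP screen.
    """

    hmrg_cogs: dict[str, frozenset[str]] = field(default_factory=dict)
    arg_cogs: frozenset[str] = frozenset()
    conj_cogs: frozenset[str] = frozenset()
    mge_pfams: frozenset[str] = frozenset()
    replication_pfams: frozenset[str] = frozenset()
    extended_mge_domains: frozenset[str] = frozenset()
    viral_function_keywords: frozenset[str] = frozenset()
    organelle_keywords: frozenset[str] = frozenset()
    cog_gene_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = (set(self.hmrg_cogs) | set(self.arg_cogs)) & set(self.conj_cogs)
        if overlap:
            raise ValueError(
                "resistance and conjugal COG lists must be disjoint; "
                f"shared ids: {sorted(overlap)}"
            )
        for cog, metals in self.hmrg_cogs.items():
            if not metals:
                raise ValueError(f"{cog}: empty metal set")
        if not self.replication_pfams <= self.mge_pfams:
            raise ValueError("replication_pfams must be a subset of mge_pfams")

    def gene_name(self, cog_id: str) -> str:
        return self.cog_gene_names.get(cog_id, cog_id)
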