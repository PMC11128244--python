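"""Four-tier classification cascade for screened circular elements.

Tier order mirrors the sequential workflow the evidence was produced by:
(1) viral — confident viral-sorter category (1, 2, 4, or 5; low-confidence
categories 3 and 6 are ignored); (2) plasmid — similarity to a known
plasmid (mash p <= 0.1 and distance <= 0.1, inclusive); (3) unclassified
MGE — an MGE-related Pfam on any gene; (4) unclassified MGE — an
extended-library (CDD/TIGRFAM/SMART/PGAP) MGE domain; otherwise the
element is cryptic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import CircularElement, ClassLabel, EvidenceBundle, Vocabulary

MASH_P_MAX = 0.1
MASH_DIST_MAX = 0.1
CONFIDENT_VIRAL_CATEGORIES = frozenset({1, 2, 4, 5})


@dataclass
class ClassificationResult:
    element_id: str
    label: ClassLabel
    tier: str  # virsorter / plsdb / pfam_screen / extended_domains / none
    plasmid_replication_domain: bool = False
    supporting_ids: frozenset[str] = field(default_factory=frozenset)


def classify(
    element: CircularElement,
    evidence: Optional[EvidenceBundle],
    vocab: Vocabulary,
) -> ClassificationResult:
    """Assign exactly one class label via the four-tier cascade."""
    eid = element.element_id
    if evidence is not None and evidence.virsorter_category in CONFIDENT_VIRAL_CATEGORIES:
        return ClassificationResult(eid, ClassLabel.VIRAL, "virsorter")

    element_pfams = frozenset().union(*(g.pfam_ids for g in element.genes)) \
        if element.genes else frozenset()
    repl = bool(element_pfams & vocab.replication_pfams)

    if evidence is not None and evidence.plsdb_hit is not None:
        _, dist, pval, _ = evidence.plsdb_hit
        if dist <= MASH_DIST_MAX and pval <= MASH_P_MAX:
            return ClassificationResult(
                eid, ClassLabel.PLASMID, "plsdb",
                plasmid_replication_domain=repl,
                supporting_ids=element_pfams & vocab.mge_pfams,
            )

    mge_pfams = element_pfams & vocab.mge_pfams
    if mge_pfams:
        return ClassificationResult(
            eid, ClassLabel.UNCLASSIFIED_MGE, "pfam_screen",
            plasmid_replication_domain=repl, supporting_ids=mge_pfams,
        )

    domains = frozenset().union(*(g.domain_ids for g in element.genes)) \
        if element.genes else frozenset()
    ext = domains & vocab.extended_mge_domains
    if ext:
        return ClassificationResult(
            eid, ClassLabel.UNCLASSIFIED_MGE, "extended_domains",
            supporting_ids=ext,
        )

    return ClassificationResult(eid, ClassLabel.CRYPTIC, "none")


def classify_all(
    elements: list[CircularElement],
    evidence: dict[str, EvidenceBundle],
    vocab: Vocabulary,
) -> dict[str, ClassificationResult]:
    return {
        el.element_id: classify(el, evidence.get(el.element_id), vocab)
        for el in elements
    }


def summarize_classes(
    results: dict[str, ClassificationResult],
    elements: list[CircularElement],
) -> pd.DataFrame:
    """Per-stratum counts and proportions of each class label.

    Every element must have been classified; proportions sum to 1 within
    each stratum.
    """
    rows = []
    for el in elements:
        if el.element_id not in results:
            raise ValueError(f"unclassified element: {el.element_id}")
        rows.append((el.stratum, results[el.element_id].label.value))
    df = pd.DataFrame(rows, columns=["stratum", "label"])
    labels = [lab.value for lab in ClassLabel if lab is not ClassLabel.REMOVED_FALSE_POSITIVE]
    out = []
    for stratum, grp in df.groupby("stratum"):
        n = len(grp)
        counts = grp["label"].value_counts()
        for lab in labels:
            c = int(counts.get(lab, 0))
            out.append({
                "stratum": stratum, "label": lab,
                "count": c, "proportion": c / n if n else 0.0,
            })
    return pd.DataFrame(out)
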