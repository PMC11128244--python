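"""Host prediction for circular elements.

Non-viral elements are assigned a host by majority vote over gene-level
taxonomic annotations: a phylum (or class) is called when more than half
of the element's CDS agree.  Viral hosts come from the k-mer predictor's
phylum call in the evidence bundle, optionally refined by CRISPR-spacer
hits filtered to at most one mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .classify import ClassificationResult
from .model import CircularElement, ClassLabel, EvidenceBundle

UNASSIGNED = "unassigned"


@dataclass
class HostCall:
    element_id: str
    level: str  # phylum / class
    taxon: str  # phylum or class name, or "unassigned"
    vote_fraction: float
    n_genes_total: int
    n_genes_annotated: int


def vote_taxonomy(
    element: CircularElement, level: str = "phylum",
    denominator: str = "all",
) -> HostCall:
    """Majority-vote host call at the requested taxonomic level.

    With ``denominator="all"`` (default, conservative) unannotated genes
    count toward the total, so the modal taxon must exceed half of ALL
    CDS; ``denominator="annotated"`` restricts the total to genes with a
    taxonomy.  Ties at exactly one half are unassigned.
    """
    if level not in ("phylum", "class"):
        raise ValueError(f"level must be phylum or class, got {level!r}")
    if denominator not in ("all", "annotated"):
        raise ValueError(f"denominator must be all or annotated, got {denominator!r}")
    idx = 0 if level == "phylum" else 1
    tally: dict[str, int] = {}
    annotated = 0
    for g in element.genes:
        if g.taxonomy is None:
            continue
        taxon = g.taxonomy[idx]
        if not taxon:
            continue
        annotated += 1
        tally[taxon] = tally.get(taxon, 0) + 1
    total = element.n_genes if denominator == "all" else annotated
    if total == 0 or not tally:
        return HostCall(element.element_id, level, UNASSIGNED, 0.0,
                        element.n_genes, annotated)
    # deterministic winner: count desc, then name
    winner, count = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    fraction = count / total
    if fraction > 0.5:
        return HostCall(element.element_id, level, winner, fraction,
                        element.n_genes, annotated)
    return HostCall(element.element_id, level, UNASSIGNED, fraction,
                    element.n_genes, annotated)


def crispr_host(evidence: EvidenceBundle, max_mismatches: int = 1) -> list[str]:
    """Source taxa of CRISPR-spacer hits with <= ``max_mismatches``.

    Deduplicated by taxon, first-seen order preserved.
    """
    seen: list[str] = []
    for taxon, mm in evidence.crispr_hits:
        if mm <= max_mismatches and taxon not in seen:
            seen.append(taxon)
    return seen


def plsdb_host_consistent(call: HostCall, evidence: Optional[EvidenceBundle]) -> Optional[bool]:
    """Whether the vote agrees with the plasmid-database host metadata.

    String-normalized phylum-level containment check; ``None`` when there
    is no PLSDB hit or no assigned vote.
    """
    if evidence is None or evidence.plsdb_hit is None or call.taxon == UNASSIGNED:
        return None
    meta = evidence.plsdb_hit[3].lower()
    return call.taxon.lower() in meta


def host_summary(
    calls: dict[str, HostCall],
    classes: dict[str, ClassificationResult],
    elements: list[CircularElement],
    evidence: dict[str, EvidenceBundle],
) -> pd.DataFrame:
    """Per-stratum host-phylum proportions, viral and non-viral separately.

    Viral host calls come from the k-mer predictor (php_phylum); non-viral
    from the gene-taxonomy vote.  Proportions are normalized against the
    total number of elements in each (stratum, group) set; unassigned is a
    reported category.
    """
    rows = []
    for el in elements:
        res = classes.get(el.element_id)
        if res is None:
            raise ValueError(f"unclassified element: {el.element_id}")
        if res.label is ClassLabel.VIRAL:
            ev = evidence.get(el.element_id)
            taxon = ev.php_phylum if ev is not None and ev.php_phylum else UNASSIGNED
            rows.append((el.stratum, "viral", taxon))
        else:
            call = calls.get(el.element_id)
            taxon = call.taxon if call is not None else UNASSIGNED
            rows.append((el.stratum, "non_viral", taxon))
    df = pd.DataFrame(rows, columns=["stratum", "group", "taxon"])
    out = []
    for (stratum, group), grp in df.groupby(["stratum", "group"]):
        n = len(grp)
        for taxon, c in grp["taxon"].value_counts().items():
            out.append({
                "stratum": stratum, "group": group, "taxon": taxon,
                "count": int(c), "proportion": c / n,
            })
    return pd.DataFrame(out)
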