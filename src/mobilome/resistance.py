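"""Resistance-gene content, clustering, and association statistics.

Operations: COG screening for heavy-metal-resistance (HMRG), antibiotic-
resistance (ARG), and conjugal-transfer (CONJ) genes; density
normalization per Mbp and per CDS; per-COG Fisher/BH enrichment between
contamination strata; the +/- 4-ORF circular neighborhood statistic;
HMRG co-occurrence matrices; element-level association between HMRG
carriage and conjugative machinery; auxiliary-metabolic-gene (AMG)
calling on viral elements; and stratum size statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .model import CircularElement, Vocabulary
from .stats import bh_adjust, fisher_exact_two_tailed, odds_ratio, welch_t_two_sided

CATEGORIES = ("HMRG", "ARG", "CONJ")


@dataclass
class GeneHit:
    element_id: str
    orf_index: int
    gene_id: str
    cog_id: str
    category: str
    metals: frozenset[str] = field(default_factory=frozenset)


def _category_cogs(vocab: Vocabulary, category: str) -> dict[str, frozenset[str]]:
    if category == "HMRG":
        return dict(vocab.hmrg_cogs)
    if category == "ARG":
        return {c: frozenset() for c in sorted(vocab.arg_cogs)}
    if category == "CONJ":
        return {c: frozenset() for c in sorted(vocab.conj_cogs)}
    raise ValueError(f"unknown category {category!r}")


def screen_genes(
    elements: Iterable[CircularElement], vocab: Vocabulary, category: str
) -> list[GeneHit]:
    """One hit per (gene, matching COG); a gene with two matching COGs
    yields two hits.  Deterministic order: element, orf, COG."""
    cogs = _category_cogs(vocab, category)
    hits = []
    for el in elements:
        for g in el.genes:
            for cog in sorted(g.cog_ids & set(cogs)):
                hits.append(GeneHit(
                    el.element_id, g.orf_index, g.gene_id, cog, category,
                    metals=cogs[cog],
                ))
    return hits


def stratum_density(
    elements: list[CircularElement], hits: list[GeneHit]
) -> tuple[float, float]:
    """(hits per Mbp of element sequence, hits per CDS) for one element set."""
    total_bp = sum(el.length_bp for el in elements)
    total_cds = sum(el.n_genes for el in elements)
    if total_bp == 0:
        return (0.0, 0.0)
    n = len(hits)
    return (1e6 * n / total_bp, n / total_cds if total_cds else 0.0)


@dataclass
class EnrichmentRow:
    cog_id: str
    gene_name: str
    count_high: int
    count_low: int
    total_cds_high: int
    total_cds_low: int
    odds_ratio: float
    p: float
    q: float


def enrichment_table(
    elements_high: list[CircularElement],
    elements_low: list[CircularElement],
    vocab: Vocabulary,
    category: str = "HMRG",
    include_cryptic: bool = True,
    cryptic_ids: Optional[set[str]] = None,
) -> list[EnrichmentRow]:
    """Per-COG two-stratum Fisher tests with BH correction across the category.

    Each COG's 2x2 table is (count, total CDS - count) in the two strata,
    using absolute gene-hit counts.  ``include_cryptic=False`` drops
    elements whose ids are in ``cryptic_ids`` first (the conservative
    re-run).  Rows are emitted for every COG in the category's vocabulary,
    including zero-count ones (p = 1).
    """
    if not elements_high or not elements_low:
        raise ValueError("both strata must be non-empty")
    if not include_cryptic:
        if cryptic_ids is None:
            raise ValueError("cryptic_ids required when include_cryptic=False")
        elements_high = [e for e in elements_high if e.element_id not in cryptic_ids]
        elements_low = [e for e in elements_low if e.element_id not in cryptic_ids]
    cogs = _category_cogs(vocab, category)
    tot_h = sum(el.n_genes for el in elements_high)
    tot_l = sum(el.n_genes for el in elements_low)
    counts_h: dict[str, int] = {c: 0 for c in cogs}
    counts_l: dict[str, int] = {c: 0 for c in cogs}
    for counts, elems in ((counts_h, elements_high), (counts_l, elements_low)):
        for hit in screen_genes(elems, vocab, category):
            counts[hit.cog_id] += 1
    rows = []
    ps = []
    for cog in sorted(cogs):
        a, c = counts_h[cog], counts_l[cog]
        b, d = tot_h - a, tot_l - c
        p = 1.0 if (a == 0 and c == 0) else fisher_exact_two_tailed(a, b, c, d)
        ps.append(p)
        rows.append(EnrichmentRow(
            cog, vocab.gene_name(cog), a, c, tot_h, tot_l,
            odds_ratio(a, b, c, d), p, q=1.0,
        ))
    for row, q in zip(rows, bh_adjust(ps)):
        row.q = q
    return rows


def _circular_orf_distance(i: int, j: int, n: int) -> int:
    d = abs(i - j) % n
    return min(d, n - d)


def adjacency_probability(
    elements: list[CircularElement],
    vocab: Vocabulary,
    window: int = 4,
    linear: bool = False,
    per_element: bool = False,
) -> Optional[float]:
    """Probability that an HMRG gene has another HMRG within ``window`` ORFs.

    Pools all HMRG gene hits across ``elements`` (default) and reports the
    fraction with at least one *other* HMRG-bearing gene at circular
    ordinal distance <= window on the same element; two HMRG COGs on one
    gene never make that gene self-adjacent.  ``linear=True`` disables the
    wrap for sensitivity analysis; ``per_element=True`` averages
    per-element probabilities instead of pooling.  Returns ``None`` (not
    0.0) when the set has no HMRG genes.
    """
    hmrg = set(vocab.hmrg_cogs)
    per_el_fracs = []
    adjacent = total = 0
    for el in elements:
        positions = sorted({g.orf_index for g in el.genes if g.cog_ids & hmrg})
        if not positions:
            continue
        n = el.n_genes
        el_adj = 0
        for i in positions:
            ok = False
            for j in positions:
                if j == i:
                    continue
                d = abs(i - j) if linear else _circular_orf_distance(i, j, n)
                if d <= window:
                    ok = True
                    break
            el_adj += ok
        adjacent += el_adj
        total += len(positions)
        per_el_fracs.append(el_adj / len(positions))
    if total == 0:
        return None
    if per_element:
        return sum(per_el_fracs) / len(per_el_fracs)
    return adjacent / total


def cooccurrence_matrix(
    elements: list[CircularElement], vocab: Vocabulary
) -> pd.DataFrame:
    """Symmetric element-count matrix over HMRG gene names.

    Entry (g1, g2) counts elements carrying at least one hit of each;
    the diagonal counts elements carrying the gene at all.
    """
    names = sorted({vocab.gene_name(c) for c in vocab.hmrg_cogs})
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for el in elements:
        present = sorted({
            vocab.gene_name(c)
            for g in el.genes for c in (g.cog_ids & set(vocab.hmrg_cogs))
        })
        for g1 in present:
            for g2 in present:
                mat.loc[g1, g2] += 1
    return mat


def conjugative_flag(element: CircularElement, vocab: Vocabulary,
                     is_viral: bool = False) -> bool:
    """True iff the (non-viral) element carries >= 1 conjugal-transfer COG."""
    if is_viral:
        raise ValueError(f"{element.element_id}: conjugative_flag is undefined for viral elements")
    return any(g.cog_ids & vocab.conj_cogs for g in element.genes)


def hmrg_conjugation_association(
    nonviral_elements: list[CircularElement], vocab: Vocabulary
) -> tuple[tuple[tuple[int, int], tuple[int, int]], float, Optional[float]]:
    """Element-level association between conjugative machinery and HMRG carriage.

    Returns (2x2 table with rows = conjugative yes/no and columns =
    carries >= 1 HMRG yes/no, two-tailed Fisher p, fraction of HMRG gene
    hits located on conjugative elements).  Viral elements must have been
    excluded by the caller.  The fraction is ``None`` when there are no
    HMRG hits.
    """
    hmrg_hits = screen_genes(nonviral_elements, vocab, "HMRG")
    hits_by_el: dict[str, int] = {}
    for h in hmrg_hits:
        hits_by_el[h.element_id] = hits_by_el.get(h.element_id, 0) + 1
    table = [[0, 0], [0, 0]]
    hmrg_on_conj = 0
    for el in nonviral_elements:
        conj = conjugative_flag(el, vocab)
        has_hmrg = hits_by_el.get(el.element_id, 0) > 0
        table[0 if conj else 1][0 if has_hmrg else 1] += 1
        if conj:
            hmrg_on_conj += hits_by_el.get(el.element_id, 0)
    p = fisher_exact_two_tailed(table[0][0], table[0][1], table[1][0], table[1][1])
    fraction = hmrg_on_conj / len(hmrg_hits) if hmrg_hits else None
    return ((table[0][0], table[0][1]), (table[1][0], table[1][1])), p, fraction


def identify_amgs(
    viral_elements: list[CircularElement], vocab: Vocabulary
) -> list[dict]:
    """Candidate auxiliary metabolic genes on viral elements.

    A gene is a candidate AMG when it carries a functional annotation (a
    non-empty, non-hypothetical product or at least one COG) and matches
    no viral replication/structure/function keyword.  HMRG-category AMGs
    are flagged with their metal set.
    """
    keywords = [k.lower() for k in vocab.viral_function_keywords]
    out = []
    for el in viral_elements:
        for g in el.genes:
            product = (g.product or "").strip()
            annotated = bool(g.cog_ids) or (
                product and product.lower() != "hypothetical protein"
            )
            if not annotated:
                continue
            text = product.lower()
            if any(k in text for k in keywords):
                continue
            hmrg_cogs = sorted(g.cog_ids & set(vocab.hmrg_cogs))
            metals = sorted(set().union(*(vocab.hmrg_cogs[c] for c in hmrg_cogs))) \
                if hmrg_cogs else []
            out.append({
                "element_id": el.element_id,
                "gene_id": g.gene_id,
                "product": product,
                "hmrg_flag": bool(hmrg_cogs),
                "hmrg_cogs": hmrg_cogs,
                "metals": metals,
            })
    return out


def size_stats(elements: list[CircularElement]) -> dict:
    """Per-stratum length means and threshold counts, plus the Welch test.

    Thresholds are strict: counts of elements with length > 20 kb and
    > 100 kb.  The Welch two-sided t-test compares high vs low stratum
    lengths when both have >= 2 elements (p is None otherwise, or when
    both strata have zero length variance).
    """
    out: dict = {"per_stratum": {}}
    lengths = {"high_U": [], "low_U": []}
    for el in elements:
        lengths[el.stratum].append(el.length_bp)
    for stratum, vals in lengths.items():
        out["per_stratum"][stratum] = {
            "n": len(vals),
            "mean_length_bp": sum(vals) / len(vals) if vals else None,
            "count_gt_20kb": sum(v > 20000 for v in vals),
            "count_gt_100kb": sum(v > 100000 for v in vals),
        }
    hi, lo = lengths["high_U"], lengths["low_U"]
    if len(hi) >= 2 and len(lo) >= 2:
        try:
            t, df, p = welch_t_two_sided(hi, lo)
            out["welch"] = {"t": t, "df": df, "p": p}
        except ValueError:
            out["welch"] = None
    else:
        out["welch"] = None
    return out
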