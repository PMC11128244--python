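"""False-positive screening and within-stratum dereplication.

Two artifact classes are screened out before classification: partial
organellar (mitochondrial/chloroplast) genomes, detected from gene
products and taxonomy, and long tandem-repeat regions that were
inappropriately circularized, detected by whole-sequence periodicity.
Surviving elements are dereplicated within each contamination stratum by
greedy, longest-first clustering under rotation- and strand-invariant
nucleotide identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import edlib

from .model import CircularElement, Vocabulary

ORGANELLE_FRACTION_THRESHOLD = 0.5
REPEAT_IDENTITY_THRESHOLD = 0.95
DEREP_IDENTITY = 0.99
DEREP_COVERAGE = 0.90

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class ScreenReport:
    element_id: str
    removed: bool
    reason: str  # organelle / tandem_repeat_artifact / duplicate / none
    cluster_representative: str

    def __post_init__(self) -> None:
        if self.removed != (self.reason != "none"):
            raise ValueError("removed must hold exactly when a reason is given")


def detect_organelle(element: CircularElement, vocab: Vocabulary) -> bool:
    """True iff >= 50% of annotated genes look organellar/eukaryotic.

    A gene matches when its product text or taxonomic lineage contains an
    organelle keyword (case-insensitive substring).  The denominator is
    the set of genes carrying a product or a taxonomy; an element with no
    such genes is never flagged.
    """
    keywords = [k.lower() for k in vocab.organelle_keywords]
    annotated = matched = 0
    for g in element.genes:
        text_parts = []
        if g.product:
            text_parts.append(g.product)
        if g.taxonomy is not None:
            text_parts.extend(g.taxonomy)
        if not text_parts:
            continue
        annotated += 1
        text = " ".join(text_parts).lower()
        if any(k in text for k in keywords):
            matched += 1
    if annotated == 0:
        return False
    return matched / annotated >= ORGANELLE_FRACTION_THRESHOLD


def detect_tandem_repeat_artifact(sequence: Optional[str]) -> bool:
    """True iff the sequence is k >= 2 whole tandem copies of one unit.

    Checks every divisor k of the length with a unit of >= 50 bp; the
    element is an artifact when every copy matches the first copy at
    >= 95% identity.  Periodicity is a rotation-invariant property of a
    circular sequence, so no rotation search is needed.  ``None`` input
    signals "cannot screen": the element passes with a warning.
    """
    if sequence is None:
        warnings.warn("no sequence available; tandem-repeat screen skipped",
                      stacklevel=2)
        return False
    n = len(sequence)
    if n < 200:
        raise ValueError("sequence shorter than 200 bp")
    for k in range(2, n // 50 + 1):
        if n % k:
            continue
        unit_len = n // k
        first = sequence[:unit_len]
        ok = True
        for c in range(1, k):
            copy = sequence[c * unit_len:(c + 1) * unit_len]
            mismatches = sum(a != b for a, b in zip(first, copy))
            if 1.0 - mismatches / unit_len < REPEAT_IDENTITY_THRESHOLD:
                ok = False
                break
        if ok:
            return True
    return False


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically least rotation."""
    s2 = s + s
    n = len(s2)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s2[k:k + len(s)]


def canonical_form(seq: str) -> str:
    """Strand- and rotation-invariant canonical form of a circular sequence."""
    return min(_least_rotation(seq), _least_rotation(reverse_complement(seq)))


def _fingerprint(element: CircularElement) -> tuple:
    """Rotation/orientation-invariant ordered COG/Pfam fingerprint.

    The element length is part of the fingerprint: two elements whose gene
    annotations coincide (common for short, sparsely annotated elements)
    are still distinct replicons when their lengths differ.
    """
    sig = [
        (",".join(sorted(g.cog_ids)), ",".join(sorted(g.pfam_ids)))
        for g in element.genes
    ]
    if not sig:
        return (element.length_bp,)
    candidates = []
    for base in (sig, sig[::-1]):
        for r in range(len(base)):
            candidates.append(tuple(base[r:] + base[:r]))
    return (element.length_bp,) + min(candidates)


def _circular_identity(short_seq: str, long_seq: str) -> float:
    """Identity of the shorter circular sequence inside the longer one.

    The longer sequence is doubled so any rotation of the shorter can be
    found; both strands of the shorter are tried.  Identity is
    1 - edit_distance / len(short).
    """
    target = long_seq + long_seq
    best = len(short_seq)
    for query in (short_seq, reverse_complement(short_seq)):
        d = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
        if d >= 0:
            best = min(best, d)
    return 1.0 - best / len(short_seq)


def screen_elements(
    elements: list[CircularElement], vocab: Vocabulary
) -> tuple[list[CircularElement], list[ScreenReport]]:
    """Remove organellar and tandem-repeat false positives."""
    survivors, reports = [], []
    for el in elements:
        if detect_organelle(el, vocab):
            reports.append(ScreenReport(el.element_id, True, "organelle", el.element_id))
            continue
        if el.sequence is not None and detect_tandem_repeat_artifact(el.sequence):
            reports.append(ScreenReport(el.element_id, True, "tandem_repeat_artifact", el.element_id))
            continue
        survivors.append(el)
    return survivors, reports


def dereplicate(
    elements: list[CircularElement],
    identity: float = DEREP_IDENTITY,
    coverage: float = DEREP_COVERAGE,
) -> tuple[list[CircularElement], list[ScreenReport]]:
    """Greedy longest-first clustering within one stratum.

    An element joins an existing representative when its circular,
    strand-invariant nucleotide identity over the shorter sequence is
    >= ``identity`` with the shorter covering >= ``coverage`` of itself
    (the infix alignment aligns the whole shorter sequence, so coverage
    is complete whenever an alignment exists).  Without sequences, exact
    equality of the rotation-invariant ordered COG/Pfam fingerprint is
    required.  Representatives are the longest member of each cluster;
    output order is deterministic (length descending, then id).
    """
    strata = {el.stratum for el in elements}
    if len(strata) > 1:
        raise ValueError(f"dereplicate requires a single stratum, got {sorted(strata)}")
    ordered = sorted(elements, key=lambda e: (-e.length_bp, e.element_id))
    reps: list[CircularElement] = []
    rep_canon: dict[str, str] = {}
    rep_fp: dict[str, tuple] = {}
    assignment: dict[str, str] = {}
    for el in ordered:
        joined = None
        el_canon = canonical_form(el.sequence) if el.sequence is not None else None
        el_fp = _fingerprint(el)
        for rep in reps:
            if el.sequence is not None and rep.sequence is not None:
                # greedy longest-first ordering guarantees el is the shorter
                # sequence, so the infix alignment covers all of it
                if el_canon == rep_canon[rep.element_id]:
                    joined = rep
                    break
                if _circular_identity(el.sequence, rep.sequence) >= identity:
                    joined = rep
                    break
            else:
                if el_fp == rep_fp[rep.element_id]:
                    joined = rep
                    break
        if joined is None:
            reps.append(el)
            if el.sequence is not None:
                rep_canon[el.element_id] = canonical_form(el.sequence)
            rep_fp[el.element_id] = _fingerprint(el)
            assignment[el.element_id] = el.element_id
        else:
            assignment[el.element_id] = joined.element_id
    reports = [
        ScreenReport(
            el.element_id,
            assignment[el.element_id] != el.element_id,
            "duplicate" if assignment[el.element_id] != el.element_id else "none",
            assignment[el.element_id],
        )
        for el in ordered
    ]
    return reps, reports
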