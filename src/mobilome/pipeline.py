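"""End-to-end pipeline: screen -> dereplicate -> classify -> host -> analyze.

``run_pipeline`` executes every stage in order on an annotation table plus
evidence table (or on in-memory objects), writes the per-stage TSV
outputs, and emits a machine-readable JSON summary embedding the resolved
configuration and vocabulary checksums, so identical config + inputs give
byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as mio
from .classify import classify_all, summarize_classes
from .hosts import host_summary, plsdb_host_consistent, vote_taxonomy
from .model import CircularElement, ClassLabel, EvidenceBundle, Vocabulary
from .resistance import (
    adjacency_probability,
    cooccurrence_matrix,
    enrichment_table,
    hmrg_conjugation_association,
    identify_amgs,
    screen_genes,
    size_stats,
    stratum_density,
)
from .screen import dereplicate, screen_elements

log = logging.getLogger("mobilome")


@dataclass
class RunConfig:
    """Resolved thresholds and paths for one pipeline run."""

    annotations: Optional[str] = None
    evidence: Optional[str] = None
    fasta: Optional[str] = None
    vocab_dir: Optional[str] = None
    outdir: str = "mobilome_out"
    seed: int = 0
    organelle_fraction: float = 0.5
    repeat_identity: float = 0.95
    derep_identity: float = 0.99
    derep_coverage: float = 0.90
    mash_p_max: float = 0.1
    mash_dist_max: float = 0.1
    vote_denominator: str = "all"
    adjacency_window: int = 4
    adjacency_linear: bool = False
    fdr_alpha: float = 0.05
    exclude_cryptic: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    summary: dict
    elements: list[CircularElement] = field(default_factory=list)
    classes: dict = field(default_factory=dict)


def _vocab_checksums(vocab_dir: Path) -> dict[str, str]:
    sums = {}
    for path in sorted(vocab_dir.glob("*.tsv")):
        sums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    return sums


def run_pipeline(
    config: RunConfig,
    elements: Optional[list[CircularElement]] = None,
    evidence: Optional[dict[str, EvidenceBundle]] = None,
    vocab: Optional[Vocabulary] = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run all stages; returns the JSON-able summary and key intermediates."""
    t0 = time.time()
    vocab_dir = Path(config.vocab_dir) if config.vocab_dir else mio.default_vocabulary_dir()
    if vocab is None:
        vocab = mio.load_vocabulary(vocab_dir)
    if elements is None:
        if config.annotations is None:
            raise ValueError("stage load: no annotation table or in-memory elements given")
        elements = mio.read_annotation_table(config.annotations)
        if config.fasta:
            seqs = mio.read_fasta(config.fasta)
            for el in elements:
                if el.element_id in seqs:
                    el.sequence = seqs[el.element_id]
                    el.length_bp = len(el.sequence)
    if evidence is None:
        evidence = mio.read_evidence_table(config.evidence) if config.evidence else {}
    if not elements:
        raise ValueError("stage load: empty element set")
    log.info("loaded %d elements", len(elements))

    # stage: false-positive screening
    survivors, fp_reports = screen_elements(elements, vocab)
    log.info("screening removed %d elements", len(elements) - len(survivors))

    # stage: within-stratum dereplication
    reps: list[CircularElement] = []
    derep_reports = []
    for stratum in ("high_U", "low_U"):
        subset = [el for el in survivors if el.stratum == stratum]
        if not subset:
            continue
        r, reports = dereplicate(subset, config.derep_identity, config.derep_coverage)
        reps.extend(r)
        derep_reports.extend(reports)
    log.info("dereplicated to %d representatives", len(reps))

    # stage: classification
    classes = classify_all(reps, evidence, vocab)
    class_table = summarize_classes(classes, reps)
    viral_ids = {eid for eid, r in classes.items() if r.label is ClassLabel.VIRAL}
    cryptic_ids = {eid for eid, r in classes.items() if r.label is ClassLabel.CRYPTIC}
    nonviral = [el for el in reps if el.element_id not in viral_ids]
    viral = [el for el in reps if el.element_id in viral_ids]

    # stage: host prediction
    calls = {
        el.element_id: vote_taxonomy(el, "phylum", config.vote_denominator)
        for el in nonviral
    }
    class_calls = {
        el.element_id: vote_taxonomy(el, "class", config.vote_denominator)
        for el in nonviral
    }
    hosts_table = host_summary(calls, classes, reps, evidence)

    # stage: resistance / conjugation analytics
    by_stratum = {
        s: [el for el in reps if el.stratum == s] for s in ("high_U", "low_U")
    }
    densities = {}
    for stratum, subset in by_stratum.items():
        hmrg_hits = screen_genes(subset, vocab, "HMRG")
        per_mbp, per_cds = stratum_density(subset, hmrg_hits)
        densities[stratum] = {
            "hmrg_hits": len(hmrg_hits),
            "hmrg_per_mbp": per_mbp,
            "hmrg_per_cds": per_cds,
        }
    enrichment = {}
    if by_stratum["high_U"] and by_stratum["low_U"]:
        for category in ("HMRG", "ARG"):
            rows = enrichment_table(
                by_stratum["high_U"], by_stratum["low_U"], vocab, category,
                include_cryptic=not config.exclude_cryptic,
                cryptic_ids=cryptic_ids,
            )
            enrichment[category] = rows
    adjacency = {
        stratum: adjacency_probability(
            subset, vocab, config.adjacency_window, config.adjacency_linear
        )
        for stratum, subset in by_stratum.items()
    }
    cooc = cooccurrence_matrix(reps, vocab)
    table, assoc_p, hmrg_conj_fraction = hmrg_conjugation_association(nonviral, vocab)
    amgs = identify_amgs(viral, vocab)
    sizes = size_stats(reps)

    sig = {
        category: [r.cog_id for r in rows if r.q < config.fdr_alpha]
        for category, rows in enrichment.items()
    }
    summary = {
        "config": config.to_dict(),
        "vocab_checksums": _vocab_checksums(vocab_dir),
        "n_input": len(elements),
        "n_removed_false_positive": len(fp_reports),
        "n_duplicates": sum(r.removed for r in derep_reports),
        "n_representatives": len(reps),
        "class_counts": {
            f"{row.stratum}:{row.label}": int(row.count)
            for row in class_table.itertuples()
        },
        "host_proportions": {
            f"{row.stratum}:{row.group}:{row.taxon}": round(row.proportion, 6)
            for row in hosts_table.itertuples()
        },
        "densities": densities,
        "adjacency_probability": adjacency,
        "conjugation": {
            "table": table,
            "fisher_p": assoc_p,
            "hmrg_on_conjugative_fraction": hmrg_conj_fraction,
        },
        "significant_cogs": sig,
        "n_amgs": len(amgs),
        "size_stats": sizes,
    }

    if write_outputs:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [dataclasses.asdict(r) for r in fp_reports + derep_reports]
        ).to_csv(outdir / "screen_report.tsv", sep="\t", index=False)
        class_table.to_csv(outdir / "classes.tsv", sep="\t", index=False)
        hosts_table.to_csv(outdir / "hosts.tsv", sep="\t", index=False)
        host_rows = []
        for el in nonviral:
            call = calls[el.element_id]
            host_rows.append({
                "element_id": el.element_id,
                "phylum": call.taxon,
                "phylum_vote_fraction": round(call.vote_fraction, 4),
                "class": class_calls[el.element_id].taxon,
                "plsdb_host_consistent": plsdb_host_consistent(
                    call, evidence.get(el.element_id)),
            })
        pd.DataFrame(host_rows).to_csv(outdir / "host_calls.tsv", sep="\t", index=False)
        for category, rows in enrichment.items():
            pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(
                outdir / f"enrichment_{category.lower()}.tsv", sep="\t", index=False)
        cooc.to_csv(outdir / "cooccurrence.tsv", sep="\t")
        pd.DataFrame(amgs).to_csv(outdir / "amgs.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8")
        report = _text_report(summary)
        (outdir / "report.txt").write_text(report, encoding="utf-8")
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return PipelineResult(summary=summary, elements=reps, classes=classes)


def _text_report(summary: dict) -> str:
    lines = [
        "mobilome pipeline summary",
        "=========================",
        f"input elements:            {summary['n_input']}",
        f"removed false positives:   {summary['n_removed_false_positive']}",
        f"duplicates collapsed:      {summary['n_duplicates']}",
        f"representatives analyzed:  {summary['n_representatives']}",
        "",
        "class counts (stratum:label):",
    ]
    for key, val in sorted(summary["class_counts"].items()):
        lines.append(f"  {key:45s} {val}")
    lines.append("")
    for stratum, d in summary["densities"].items():
        lines.append(
            f"HMRG density {stratum}: {d['hmrg_per_mbp']:.1f} per Mbp "
            f"({100 * d['hmrg_per_cds']:.1f}% of CDS)"
        )
    conj = summary["conjugation"]
    if conj["hmrg_on_conjugative_fraction"] is not None:
        lines.append(
            f"HMRG on conjugative elements: "
            f"{100 * conj['hmrg_on_conjugative_fraction']:.0f}% "
            f"(Fisher p = {conj['fisher_p']:.2e})"
        )
    for stratum, prob in summary["adjacency_probability"].items():
        shown = "undefined" if prob is None else f"{prob:.3f}"
        lines.append(f"adjacency probability {stratum}: {shown}")
    sig = summary.get("significant_cogs", {})
    for category, cogs in sig.items():
        lines.append(f"significant {category} COGs (q < alpha): {len(cogs)}")
    return "\n".join(lines) + "\n"
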