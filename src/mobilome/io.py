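"""Readers and writers for the pipeline's tab-separated dialects and FASTA.

All tables are UTF-8 TSV with a header line; comment lines start with
``#``; the token ``-`` encodes an absent value throughout.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import STRATA, CircularElement, EvidenceBundle, GeneFeature, Vocabulary

ABSENT = "-"

ANNOTATION_COLUMNS = [
    "element_id", "sample_id", "stratum", "element_length",
    "gene_id", "orf_index", "start", "end", "strand",
    "cogs", "pfams", "domains", "tax_phylum", "tax_class", "product",
]

EVIDENCE_COLUMNS = [
    "element_id", "virsorter_category", "plsdb_accession", "mash_distance",
    "mash_pvalue", "plsdb_host", "crispr_hits", "php_phylum", "lifestyle",
]


class TableFormatError(ValueError):
    """Raised when an input table violates the format contract."""


def _iter_rows(path: str | Path, expected_columns: list[str]):
    """Yield (line_number, dict) for each data row of a TSV file."""
    header: Optional[list[str]] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                if header != expected_columns:
                    raise TableFormatError(
                        f"{path}: header {header} != expected {expected_columns}"
                    )
                continue
            if len(fields) != len(header):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            yield lineno, dict(zip(header, fields))


def _split_set(token: str) -> frozenset[str]:
    if token == ABSENT or token == "":
        return frozenset()
    return frozenset(t for t in token.split(",") if t)


def _parse_int(token: str, path, lineno: int, col: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise TableFormatError(
            f"{path}:{lineno}: non-integer {col} value {token!r}"
        ) from None


def read_annotation_table(path: str | Path) -> list[CircularElement]:
    """Parse a per-gene annotation table into CircularElements.

    One row per CDS; rows for one element are grouped by ``element_id`` and
    ordered by ``orf_index``.  Duplicate (element_id, orf_index) pairs,
    non-integer coordinates, and unknown stratum tokens are rejected with
    the offending row number.
    """
    meta: dict[str, tuple[str, str, int]] = {}
    genes: dict[str, dict[int, GeneFeature]] = {}
    order: list[str] = []
    for lineno, row in _iter_rows(path, ANNOTATION_COLUMNS):
        eid = row["element_id"]
        if row["stratum"] not in STRATA:
            raise TableFormatError(
                f"{path}:{lineno}: unknown stratum token {row['stratum']!r}"
            )
        length = _parse_int(row["element_length"], path, lineno, "element_length")
        orf = _parse_int(row["orf_index"], path, lineno, "orf_index")
        start = _parse_int(row["start"], path, lineno, "start")
        end = _parse_int(row["end"], path, lineno, "end")
        phylum, klass = row["tax_phylum"], row["tax_class"]
        taxonomy = None
        if phylum != ABSENT:
            taxonomy = (phylum, klass if klass != ABSENT else "")
        gene = GeneFeature(
            gene_id=row["gene_id"],
            orf_index=orf,
            start=start,
            end=end,
            strand=row["strand"],
            cog_ids=_split_set(row["cogs"]),
            pfam_ids=_split_set(row["pfams"]),
            domain_ids=_split_set(row["domains"]),
            taxonomy=taxonomy,
            product="" if row["product"] == ABSENT else row["product"],
        )
        if eid not in meta:
            meta[eid] = (row["sample_id"], row["stratum"], length)
            genes[eid] = {}
            order.append(eid)
        if orf in genes[eid]:
            raise TableFormatError(
                f"{path}:{lineno}: duplicate orf_index {orf} for element {eid}"
            )
        genes[eid][orf] = gene
    elements = []
    for eid in order:
        sample, stratum, length = meta[eid]
        elements.append(
            CircularElement(
                element_id=eid,
                sample_id=sample,
                stratum=stratum,
                length_bp=length,
                genes=[genes[eid][k] for k in sorted(genes[eid])],
            )
        )
    return elements


def write_annotation_table(elements: Iterable[CircularElement], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for el in elements:
            for g in el.genes:
                phylum, klass = (ABSENT, ABSENT)
                if g.taxonomy is not None:
                    phylum = g.taxonomy[0]
                    klass = g.taxonomy[1] or ABSENT
                fh.write("\t".join([
                    el.element_id, el.sample_id, el.stratum, str(el.length_bp),
                    g.gene_id, str(g.orf_index), str(g.start), str(g.end), g.strand,
                    ",".join(sorted(g.cog_ids)) or ABSENT,
                    ",".join(sorted(g.pfam_ids)) or ABSENT,
                    ",".join(sorted(g.domain_ids)) or ABSENT,
                    phylum, klass, g.product or ABSENT,
                ]) + "\n")


def read_evidence_table(path: str | Path) -> dict[str, EvidenceBundle]:
    """Parse the external-evidence table into one bundle per element."""
    bundles: dict[str, EvidenceBundle] = {}
    for lineno, row in _iter_rows(path, EVIDENCE_COLUMNS):
        eid = row["element_id"]
        if eid in bundles:
            raise TableFormatError(
                f"{path}:{lineno}: duplicate evidence row for element {eid}"
            )
        category = None
        if row["virsorter_category"] != ABSENT:
            category = _parse_int(row["virsorter_category"], path, lineno, "virsorter_category")
        plsdb_hit = None
        if row["plsdb_accession"] != ABSENT:
            if row["mash_distance"] == ABSENT or row["mash_pvalue"] == ABSENT:
                raise TableFormatError(
                    f"{path}:{lineno}: PLSDB hit without mash distance/p-value"
                )
            dist = float(row["mash_distance"])
            pval = float(row["mash_pvalue"])
            if not (0.0 <= dist <= 1.0):
                raise TableFormatError(
                    f"{path}:{lineno}: mash_distance {dist} outside [0,1]"
                )
            host = "" if row["plsdb_host"] == ABSENT else row["plsdb_host"]
            plsdb_hit = (row["plsdb_accession"], dist, pval, host)
        crispr_hits: list[tuple[str, int]] = []
        if row["crispr_hits"] != ABSENT:
            for tok in row["crispr_hits"].split(";"):
                taxon, _, mm = tok.rpartition(":")
                if not taxon:
                    raise TableFormatError(
                        f"{path}:{lineno}: malformed CRISPR hit token {tok!r}"
                    )
                crispr_hits.append((taxon, _parse_int(mm, path, lineno, "crispr mismatches")))
        bundles[eid] = EvidenceBundle(
            element_id=eid,
            virsorter_category=category,
            plsdb_hit=plsdb_hit,
            crispr_hits=crispr_hits,
            php_phylum=None if row["php_phylum"] == ABSENT else row["php_phylum"],
            lifestyle=None if row["lifestyle"] == ABSENT else row["lifestyle"],
        )
    return bundles


def write_evidence_table(bundles: Iterable[EvidenceBundle], path: str | Path) -> None:
    def fmt(value) -> str:
        return ABSENT if value is None or value == "" else str(value)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EVIDENCE_COLUMNS) + "\n")
        for b in bundles:
            if b.plsdb_hit is not None:
                acc, dist, pval, host = b.plsdb_hit
                plsdb = [acc, repr(dist), repr(pval), host or ABSENT]
            else:
                plsdb = [ABSENT] * 4
            crispr = ";".join(f"{t}:{m}" for t, m in b.crispr_hits) or ABSENT
            fh.write("\t".join([
                b.element_id, fmt(b.virsorter_category), *plsdb, crispr,
                fmt(b.php_phylum), fmt(b.lifestyle),
            ]) + "\n")


# ---------------------------------------------------------------------------
# vocabulary

def default_vocabulary_dir() -> Path:
    return Path(str(resources.files("mobilome").joinpath("data/vocab")))


def _read_keyword_file(path: Path, column: str) -> frozenset[str]:
    out = []
    for _, row in _iter_rows(path, [column]):
        out.append(row[column])
    return frozenset(out)


def load_vocabulary(directory: str | Path | None = None) -> Vocabulary:
    """Load the curated COG/Pfam/keyword vocabularies.

    With no argument, loads the packaged defaults (a best-effort curated
    transcription from the public COG and Pfam databases); pass a directory
    of the same-named TSV files to override.
    """
    vdir = Path(directory) if directory is not None else default_vocabulary_dir()
    hmrg: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for _, row in _iter_rows(vdir / "hmrg_cogs.tsv", ["cog_id", "gene_name", "metals"]):
        metals = _split_set(row["metals"])
        if not metals:
            raise TableFormatError(f"{row['cog_id']}: empty metal set")
        hmrg[row["cog_id"]] = metals
        names[row["cog_id"]] = row["gene_name"]
    arg, conj = set(), set()
    for _, row in _iter_rows(vdir / "arg_cogs.tsv", ["cog_id", "gene_name"]):
        arg.add(row["cog_id"])
        names[row["cog_id"]] = row["gene_name"]
    for _, row in _iter_rows(vdir / "conj_cogs.tsv", ["cog_id", "gene_name"]):
        conj.add(row["cog_id"])
        names[row["cog_id"]] = row["gene_name"]
    pfams, repl = set(), set()
    for _, row in _iter_rows(vdir / "mge_pfams.tsv", ["pfam_id", "name", "replication"]):
        pfams.add(row["pfam_id"])
        if row["replication"] == "1":
            repl.add(row["pfam_id"])
    return Vocabulary(
        hmrg_cogs=hmrg,
        arg_cogs=frozenset(arg),
        conj_cogs=frozenset(conj),
        mge_pfams=frozenset(pfams),
        replication_pfams=frozenset(repl),
        extended_mge_domains=_read_keyword_file(vdir / "extended_mge_domains.tsv", "domain_id"),
        viral_function_keywords=_read_keyword_file(vdir / "viral_keywords.tsv", "keyword"),
        organelle_keywords=_read_keyword_file(vdir / "organelle_keywords.tsv", "keyword"),
        cog_gene_names=names,
    )


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(elements: Iterable[CircularElement], path: str | Path) -> int:
    """Write element sequences to FASTA (70-column wrap).

    Elements without a sequence are skipped with a warning; returns the
    number skipped.  Duplicate element ids are rejected.
    """
    records = []
    seen: set[str] = set()
    skipped = 0
    for el in elements:
        if el.element_id in seen:
            raise ValueError(f"duplicate element id in FASTA output: {el.element_id}")
        seen.add(el.element_id)
        if el.sequence is None:
            skipped += 1
            continue
        records.append(SeqRecord(Seq(el.sequence), id=el.element_id, description=""))
    if skipped:
        warnings.warn(f"skipped {skipped} element(s) without sequence", stacklevel=2)
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)
    return skipped


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by element id; uppercased; duplicate ids rejected."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out
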