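"""Host prediction for the classified cohort.

Votes gene-level taxonomy for non-viral representatives (strict >50%
majority over all CDS), takes viral hosts from the k-mer predictor
column, applies the 0/1-mismatch CRISPR filter, and writes per-element
host calls plus per-stratum host-phylum proportions.  Accuracy of the
vote is reported against the planted hosts.

Run:  python analysis/03_host_prediction.py
"""

import json
from pathlib import Path

import pandas as pd

from mobilome.classify import classify_all
from mobilome.hosts import crispr_host, host_summary, vote_taxonomy
from mobilome.io import load_vocabulary, read_annotation_table, read_evidence_table
from mobilome.model import ClassLabel
from mobilome.screen import dereplicate, screen_elements


def main() -> None:
    datadir = Path("results/synthetic")
    vocab = load_vocabulary()
    elements = read_annotation_table(datadir / "annotations.tsv")
    evidence = read_evidence_table(datadir / "evidence.tsv")
    truth = json.loads((datadir / "truth.json").read_text())

    survivors, _ = screen_elements(elements, vocab)
    reps = []
    for stratum in ("high_U", "low_U"):
        reps.extend(dereplicate([el for el in survivors if el.stratum == stratum])[0])
    classes = classify_all(reps, evidence, vocab)

    nonviral = [el for el in reps if classes[el.element_id].label is not ClassLabel.VIRAL]
    calls = {el.element_id: vote_taxonomy(el, "phylum") for el in nonviral}
    summary = host_summary(calls, classes, reps, evidence)
    summary.to_csv("results/host_proportions.tsv", sep="\t", index=False)
    print(summary[summary.taxon != "unassigned"]
          .sort_values(["stratum", "group", "proportion"], ascending=[1, 1, 0])
          .groupby(["stratum", "group"]).head(2).to_string(index=False))

    assigned = [c for c in calls.values() if c.taxon != "unassigned"]
    correct = sum(c.taxon == truth[c.element_id]["true_host_phylum"] for c in assigned)
    print(f"\nnon-viral vote: {len(assigned)}/{len(calls)} assigned; "
          f"accuracy among assigned {100 * correct / len(assigned):.1f}%")

    n_crispr = sum(bool(crispr_host(evidence[el.element_id]))
                   for el in reps if classes[el.element_id].label is ClassLabel.VIRAL
                   and el.element_id in evidence)
    print(f"viral elements with a 0/1-mismatch CRISPR host: {n_crispr}")

    rows = [{
        "element_id": c.element_id, "taxon": c.taxon,
        "vote_fraction": round(c.vote_fraction, 4),
        "true_host": truth[c.element_id]["true_host_phylum"],
    } for c in calls.values()]
    pd.DataFrame(rows).to_csv("results/host_calls.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
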