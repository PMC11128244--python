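"""Resistance-gene statistics over the classified cohort.

Computes HMRG densities per stratum (per Mbp and per CDS), per-COG
Fisher/BH enrichment between strata (with and without cryptic elements),
the +/-4-ORF neighborhood clustering statistic, the HMRG co-occurrence
matrix, the element-level HMRG-conjugation association, viral AMG calls,
and the stratum size statistics with Welch's t-test.  This is the full
pipeline run; outputs land under results/pipeline/.

Run:  python analysis/04_resistance_analysis.py
"""

import json

from mobilome.pipeline import RunConfig, run_pipeline


def main() -> None:
    cfg = RunConfig(
        annotations="results/synthetic/annotations.tsv",
        evidence="results/synthetic/evidence.tsv",
        outdir="results/pipeline",
    )
    result = run_pipeline(cfg)
    s = result.summary

    for stratum, d in s["densities"].items():
        print(f"{stratum}: {d['hmrg_per_mbp']:.1f} HMRGs/Mbp "
              f"({100 * d['hmrg_per_cds']:.1f}% of CDS)")
    print("adjacency probability (+/-4 ORFs):",
          {k: None if v is None else round(v, 3)
           for k, v in s["adjacency_probability"].items()})
    conj = s["conjugation"]
    print(f"HMRG on conjugative elements: "
          f"{100 * conj['hmrg_on_conjugative_fraction']:.1f}% "
          f"(Fisher p = {conj['fisher_p']:.2e})")
    print("significant HMRG COGs at q<0.05:", len(s["significant_cogs"]["HMRG"]),
          "| ARG:", len(s["significant_cogs"]["ARG"]))
    welch = s["size_stats"]["welch"]
    print(f"length contrast: Welch t = {welch['t']:.2f}, p = {welch['p']:.2e}")
    print(f"viral AMG candidates: {s['n_amgs']}")
    print(json.dumps(s["class_counts"], indent=1, sort_keys=True))
    print("full tables under results/pipeline/")


if __name__ == "__main__":
    main()
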