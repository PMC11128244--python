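"""Monte-Carlo calibration and parameter-recovery harnesses.

These routines run the full analysis path (screening, dereplication,
classification, gene screening, enrichment) over synthetic cohorts with
known planted structure and report calibration quantities: the false-
discovery rate under a null generator, the power to detect a planted
HMRG rate contrast, recovery of the planted density ratio against its
closed-form expectation, host-vote accuracy, and class-label recovery.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import lognorm, poisson

from .classify import classify_all
from .hosts import vote_taxonomy
from .model import ClassLabel, Vocabulary
from .resistance import enrichment_table, screen_genes, stratum_density
from .screen import dereplicate, screen_elements
from .synth import GeneratorConfig, null_config, power_config, simulate


def _analysis_sets(elements, vocab):
    """Screen + dereplicate, returning per-stratum representative sets."""
    survivors, _ = screen_elements(elements, vocab)
    out = {}
    for stratum in ("high_U", "low_U"):
        subset = [el for el in survivors if el.stratum == stratum]
        out[stratum] = dereplicate(subset)[0] if subset else []
    return out


def _seed_stream(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def enrichment_discovery_rate(
    base: GeneratorConfig,
    vocab: Vocabulary,
    mode: str,
    n_seeds: int = 20,
    n_per_stratum: int = 400,
    alpha: float = 0.05,
) -> float:
    """Mean fraction of HMRG COGs reaching q < alpha across seeds.

    ``mode="null"`` uses :func:`null_config` (no stratum effect: the
    fraction estimates the false-discovery proneness of the whole path
    and should stay below alpha); ``mode="power"`` uses
    :func:`power_config` (planted rate contrast: the fraction is the
    per-seed power averaged over COGs actually planted in that seed).
    """
    if mode not in ("null", "power"):
        raise ValueError(f"mode must be null or power, got {mode!r}")
    fractions = []
    for seed in _seed_stream(base.seed, n_seeds):
        cfg = GeneratorConfig(seed=seed, n_high=n_per_stratum, n_low=n_per_stratum)
        cfg = null_config(cfg) if mode == "null" else power_config(cfg)
        elements, _, truth = simulate(cfg, vocab)
        sets = _analysis_sets(elements, vocab)
        rows = enrichment_table(sets["high_U"], sets["low_U"], vocab, "HMRG")
        if mode == "null":
            denominator = {r.cog_id for r in rows}
        else:
            # power is assessed over the truly enriched COGs: those with
            # planted signal in the high-contamination stratum
            denominator = set()
            for eid, t in truth.elements.items():
                if eid.startswith("H") and t.true_class != "viral":
                    denominator.update(t.planted_hmrg_cogs)
        if not denominator:
            continue
        sig = {r.cog_id for r in rows if r.q < alpha}
        fractions.append(len(sig & denominator) / len(denominator))
    return float(np.mean(fractions))


def expected_hmrg_density_per_bp(cfg: GeneratorConfig, stratum: str) -> float:
    """Closed-form planted HMRG genes per bp for one stratum.

    Integrates the cluster-size law min(1 + Pois(mean), n_genes, pool)
    over the gene-count law n_genes = max(1, Pois(L / pitch)) and the
    length mixture, by quadrature over component quantiles.
    """
    pool = 11  # size of the co-occurring HMRG pool clusters draw from
    rate = cfg.hmrg_cluster_rate[stratum]
    s = cfg.length_shape
    smax = 60
    s_pmf = poisson.pmf(np.arange(smax), cfg.cluster_poisson_mean)  # S - 1
    sizes = 1 + np.arange(smax)

    def e_min_size(cap: int) -> float:
        return float(np.sum(s_pmf * np.minimum(sizes, cap)))

    emin = {cap: e_min_size(cap) for cap in range(1, pool + 1)}
    K = 400
    qs = (np.arange(K) + 0.5) / K
    w_small, w_large = cfg.length_weights[stratum]
    total_hits = total_bp = 0.0
    for mode_bp, w in ((cfg.mode_small_bp, w_small), (cfg.mode_large_bp, w_large)):
        if w == 0:
            continue
        lengths = np.maximum(lognorm.ppf(qs, s, scale=mode_bp), cfg.min_length_bp)
        for L in lengths:
            lam = L / cfg.gene_pitch_bp
            nmax = int(lam + 10 * math.sqrt(lam) + 10)
            n_vals = np.arange(nmax + 1)
            n_pmf = poisson.pmf(n_vals, lam)
            n_pmf[1] += n_pmf[0]  # n_genes = max(1, Pois)
            n_pmf[0] = 0.0
            caps = np.minimum(n_vals, pool)
            e_size = float(np.sum(n_pmf[1:] * np.array([emin[c] for c in caps[1:]])))
            total_hits += w / K * rate * e_size
            total_bp += w / K * L
    return total_hits / total_bp


def density_ratio_recovery(
    base: GeneratorConfig,
    vocab: Vocabulary,
    n_seeds: int = 20,
    n_per_stratum: int = 400,
) -> tuple[float, float]:
    """(measured, expected) planted high/low HMRG per-Mbp density ratio.

    The measured ratio pools hits and base pairs over all seeds after
    running the screening/dereplication path; the expectation comes from
    :func:`expected_hmrg_density_per_bp`.
    """
    pooled = {s: {"hits": 0, "bp": 0} for s in ("high_U", "low_U")}
    for seed in _seed_stream(base.seed, n_seeds):
        cfg = GeneratorConfig(seed=seed, n_high=n_per_stratum, n_low=n_per_stratum)
        elements, _, _ = simulate(cfg, vocab)
        sets = _analysis_sets(elements, vocab)
        for stratum, subset in sets.items():
            hits = screen_genes(subset, vocab, "HMRG")
            pooled[stratum]["hits"] += len(hits)
            pooled[stratum]["bp"] += sum(el.length_bp for el in subset)
    measured = (
        (pooled["high_U"]["hits"] / pooled["high_U"]["bp"])
        / (pooled["low_U"]["hits"] / pooled["low_U"]["bp"])
    )
    cfg = GeneratorConfig(seed=base.seed, n_high=n_per_stratum, n_low=n_per_stratum)
    expected = (
        expected_hmrg_density_per_bp(cfg, "high_U")
        / expected_hmrg_density_per_bp(cfg, "low_U")
    )
    return measured, expected


def host_vote_accuracy(
    vocab: Vocabulary,
    fidelity: float = 0.7,
    seed: int = 0,
    n_elements: int = 1000,
    min_genes: int = 10,
) -> float:
    """Fraction of assigned majority votes matching the planted host."""
    cfg = GeneratorConfig(
        seed=seed, n_high=n_elements, n_low=0,
        length_weights={"high_U": (0.0, 1.0), "low_U": (0.8, 0.2)},
        annotation_fidelity=fidelity,
        p_viral=0.0, p_viral_decoy=0.0, p_false_positive=0.0,
    )
    elements, _, truth = simulate(cfg, vocab)
    assigned = correct = 0
    for el in elements:
        if el.n_genes < min_genes:
            continue
        call = vote_taxonomy(el, "phylum")
        if call.taxon == "unassigned":
            continue
        assigned += 1
        correct += call.taxon == truth.elements[el.element_id].true_host_phylum
    return correct / assigned if assigned else float("nan")


def class_label_recovery(
    vocab: Vocabulary, seed: int = 0, n_per_stratum: int = 300
) -> float:
    """Fraction of elements whose emitted evidence recovers the planted class.

    Excludes screening decoys (removed_false_positive), whose label is the
    screening stage's responsibility rather than the classifier's.
    """
    cfg = GeneratorConfig(seed=seed, n_high=n_per_stratum, n_low=n_per_stratum)
    elements, evidence, truth = simulate(cfg, vocab)
    keep = [el for el in elements
            if truth.elements[el.element_id].true_class != "removed_false_positive"]
    results = classify_all(keep, evidence, vocab)
    n = correct = 0
    for el in keep:
        n += 1
        correct += (results[el.element_id].label.value
                    == truth.elements[el.element_id].true_class)
    return correct / n if n else float("nan")


def false_positive_screen_recovery(
    vocab: Vocabulary, seed: int = 0, n_per_stratum: int = 300
) -> tuple[float, float]:
    """(sensitivity, specificity) of the organelle screen on planted decoys.

    Only organelle decoys are scored (tandem-repeat decoys require
    sequences, which default cohorts omit).
    """
    cfg = GeneratorConfig(seed=seed, n_high=n_per_stratum, n_low=n_per_stratum)
    elements, _, truth = simulate(cfg, vocab)
    survivors, reports = screen_elements(elements, vocab)
    removed = {r.element_id for r in reports}
    decoys = {eid for eid, t in truth.elements.items()
              if t.removal_reason == "organelle"}
    clean = {el.element_id for el in elements} - {
        eid for eid, t in truth.elements.items()
        if t.true_class == "removed_false_positive"}
    sens = len(removed & decoys) / len(decoys) if decoys else float("nan")
    spec = 1 - len(removed & clean) / len(clean) if clean else float("nan")
    return sens, spec


def label_from_result(label: ClassLabel) -> str:
    return label.value
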