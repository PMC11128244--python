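"""Organelle/tandem-repeat screening and circular dereplication."""

import numpy as np
import pytest

from mobilome.screen import (
    canonical_form,
    dereplicate,
    detect_organelle,
    detect_tandem_repeat_artifact,
    reverse_complement,
    screen_elements,
)


def random_seq(n, rng):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


class TestOrganelle:
    def test_majority_organelle_products_flagged(self, element_factory, vocab):
        el = element_factory(gene_specs=[
            {"product": "chloroplast envelope protein"},
            {"product": "chloroplast envelope protein"},
            {"product": "chloroplast envelope protein"},
            {"product": "ABC transporter"},
        ])
        assert detect_organelle(el, vocab) is True

    def test_no_keyword_matches_pass(self, element_factory, vocab):
        el = element_factory(gene_specs=[{"product": "ABC transporter"}] * 4)
        assert detect_organelle(el, vocab) is False

    def test_half_matching_is_inclusive_boundary(self, element_factory, vocab):
        el = element_factory(gene_specs=[
            {"product": "mitochondrial ribosomal protein"},
            {"taxonomy": ("Streptophyta", "Magnoliopsida")},
            {"product": "response regulator"},
            {"product": "MFS transporter"},
        ])
        assert detect_organelle(el, vocab) is True

    def test_no_genes_passes(self, element_factory, vocab):
        assert detect_organelle(element_factory(gene_specs=[]), vocab) is False


class TestTandemRepeat:
    def test_perfect_period_detected(self):
        assert detect_tandem_repeat_artifact("ACGT" * 100) is True

    def test_random_sequence_passes_exhaustive_scan(self):
        """Oracle: exhaustive periodicity scan finds no >= 95% period."""
        rng = np.random.default_rng(42)
        seq = random_seq(400, rng)
        n = len(seq)
        oracle_periodic = False
        for k in range(2, n // 50 + 1):
            if n % k:
                continue
            u = n // k
            ident = min(
                sum(seq[i] == seq[c * u + i] for i in range(u)) / u
                for c in range(1, k)
            )
            oracle_periodic |= ident >= 0.95
        assert oracle_periodic is False
        assert detect_tandem_repeat_artifact(seq) is False

    def test_two_copies_with_three_percent_divergence_detected(self):
        rng = np.random.default_rng(7)
        unit = random_seq(300, rng)
        copy = list(unit)
        muts = rng.choice(300, size=9, replace=False)  # identity 0.97
        for pos in muts:
            copy[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[pos]]
        assert detect_tandem_repeat_artifact(unit + "".join(copy)) is True

    def test_absent_sequence_passes_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            assert detect_tandem_repeat_artifact(None) is False


class TestDereplicate:
    def test_identical_elements_collapse(self, element_factory):
        rng = np.random.default_rng(0)
        seq = random_seq(1000, rng)
        a = element_factory("A", length_bp=1000, sequence=seq)
        b = element_factory("B", length_bp=1000, sequence=seq)
        reps, reports = dereplicate([a, b])
        assert [r.element_id for r in reps] == ["A"]
        assert sum(r.removed for r in reports) == 1
        assert all(r.cluster_representative == "A" for r in reports)

    def test_rotation_and_revcomp_collapse(self, element_factory):
        rng = np.random.default_rng(1)
        seq = random_seq(1000, rng)
        rotated = seq[17:] + seq[:17]
        rc = reverse_complement(seq)
        els = [
            element_factory("A", length_bp=1000, sequence=seq),
            element_factory("B", length_bp=1000, sequence=rotated),
            element_factory("C", length_bp=1000, sequence=rc),
        ]
        reps, _ = dereplicate(els)
        assert len(reps) == 1
        assert canonical_form(seq) == canonical_form(rotated) == canonical_form(rc)

    def test_divergent_elements_stay_separate(self, element_factory):
        """Fixture built with >= 2% pairwise divergence stays unclustered."""
        rng = np.random.default_rng(2)
        base = random_seq(2000, rng)
        els = []
        for k in range(5):
            seq = list(base)
            for pos in rng.choice(2000, size=60, replace=False):  # 3% divergence
                seq[pos] = "ACGT"[(("ACGT".index(seq[pos]) + 1 + k) % 4)]
            els.append(element_factory(f"E{k}", length_bp=2000, sequence="".join(seq)))
        # oracle: all-pairs Hamming identity below the 99% threshold
        for i in range(5):
            for j in range(i + 1, 5):
                ident = sum(a == b for a, b in zip(els[i].sequence, els[j].sequence)) / 2000
                assert ident < 0.99
        reps, _ = dereplicate(els)
        assert len(reps) == 5

    def test_fingerprint_fallback_without_sequences(self, element_factory):
        a = element_factory("A", gene_specs=[{"cogs": ["COG2217"]}, {"cogs": ["COG0053"]}])
        b = element_factory("B", gene_specs=[{"cogs": ["COG0053"]}, {"cogs": ["COG2217"]}])  # rotation
        c = element_factory("C", gene_specs=[{"cogs": ["COG2217"]}, {"cogs": ["COG9001"]}])
        reps, _ = dereplicate([a, b, c])
        assert sorted(r.element_id for r in reps) == ["A", "C"]

    def test_mixed_strata_rejected(self, element_factory):
        with pytest.raises(ValueError, match="stratum"):
            dereplicate([
                element_factory("A", stratum="high_U"),
                element_factory("B", stratum="low_U"),
            ])

    def test_idempotence_and_order_independence(self, element_factory):
        rng = np.random.default_rng(3)
        els = []
        for k in range(6):
            seq = random_seq(800 + 50 * k, rng)
            els.append(element_factory(f"E{k}", length_bp=len(seq), sequence=seq))
        els.append(element_factory("DUP", length_bp=els[0].length_bp,
                                   sequence=els[0].sequence))
        reps, _ = dereplicate(els)
        reps2, _ = dereplicate(reps)
        assert [r.element_id for r in reps2] == [r.element_id for r in reps]
        shuffled = [els[i] for i in rng.permutation(len(els))]
        reps3, _ = dereplicate(shuffled)
        assert {r.element_id for r in reps3} == {r.element_id for r in reps}

    def test_every_input_maps_to_exactly_one_representative(self, element_factory):
        rng = np.random.default_rng(4)
        els = [element_factory(f"E{k}", length_bp=900, sequence=random_seq(900, rng))
               for k in range(4)]
        reps, reports = dereplicate(els)
        assert len(reports) == len(els)
        rep_ids = {r.element_id for r in reps}
        assert all(rep.cluster_representative in rep_ids for rep in reports)


def test_screen_elements_combines_both_filters(element_factory, vocab):
    organelle = element_factory("ORG", gene_specs=[
        {"product": "chloroplast envelope protein"}] * 3)
    repeat = element_factory("REP", length_bp=400, sequence="ACGT" * 100,
                             gene_specs=[{}])
    clean = element_factory("OK", gene_specs=[{"product": "MFS transporter"}] * 3)
    survivors, reports = screen_elements([organelle, repeat, clean], vocab)
    assert [el.element_id for el in survivors] == ["OK"]
    assert {r.element_id: r.reason for r in reports} == {
        "ORG": "organelle", "REP": "tandem_repeat_artifact"}
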