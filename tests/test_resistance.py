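"""Gene screening, densities, enrichment, adjacency, co-occurrence, AMGs."""

import numpy as np
import pytest

from mobilome.resistance import (
    adjacency_probability,
    conjugative_flag,
    cooccurrence_matrix,
    enrichment_table,
    hmrg_conjugation_association,
    identify_amgs,
    screen_genes,
    size_stats,
    stratum_density,
)


def adjacency_oracle(elements, hmrg_cogs, window):
    """O(n^2) pairwise scan over all HMRG genes, circular distance."""
    adjacent = total = 0
    for el in elements:
        pos = [g.orf_index for g in el.genes if g.cog_ids & hmrg_cogs]
        n = el.n_genes
        for i in pos:
            total += 1
            for j in pos:
                if i == j:
                    continue
                d = min(abs(i - j), n - abs(i - j))
                if d <= window:
                    adjacent += 1
                    break
    return None if total == 0 else adjacent / total


class TestScreenGenes:
    def test_hmrg_hit_carries_metal_set(self, element_factory, vocab):
        el = element_factory(gene_specs=[{"cogs": ["COG2217"]}])
        (hit,) = screen_genes([el], vocab, "HMRG")
        assert hit.cog_id == "COG2217" and hit.metals == {"Zn", "Cd", "Pb"}

    def test_gene_without_curated_cogs_yields_no_hit(self, element_factory, vocab):
        el = element_factory(gene_specs=[{"cogs": ["COG9001"]}, {}])
        assert screen_genes([el], vocab, "HMRG") == []

    def test_gene_with_two_hmrg_cogs_yields_two_hits(self, element_factory, vocab):
        el = element_factory(gene_specs=[{"cogs": ["COG2217", "COG0053"]}])
        hits = screen_genes([el], vocab, "HMRG")
        assert [h.cog_id for h in hits] == ["COG0053", "COG2217"]


class TestDensity:
    def test_arithmetic(self, element_factory, vocab):
        els = [element_factory(f"E{i}", length_bp=125_000,
                               gene_specs=[{"cogs": ["COG2217"]}] * 4) for i in range(4)]
        hits = screen_genes(els, vocab, "HMRG")
        per_mbp, per_cds = stratum_density(els, hits)
        assert per_mbp == pytest.approx(1e6 * 16 / 500_000)
        assert per_cds == pytest.approx(1.0)

    def test_zero_hits(self, element_factory, vocab):
        els = [element_factory(gene_specs=[{}])]
        assert stratum_density(els, []) == (0.0, 0.0)

    def test_ratio_invariant_under_duplication(self, element_factory, vocab):
        els = [element_factory("A", length_bp=10000,
                               gene_specs=[{"cogs": ["COG2217"]}, {}, {}])]
        doubled = els + [element_factory("B", length_bp=10000,
                                         gene_specs=[{"cogs": ["COG2217"]}, {}, {}])]
        d1 = stratum_density(els, screen_genes(els, vocab, "HMRG"))
        d2 = stratum_density(doubled, screen_genes(doubled, vocab, "HMRG"))
        assert d1 == pytest.approx(d2)


class TestEnrichment:
    def test_zero_count_rows_present_with_p_one(self, element_factory, vocab):
        high = [element_factory("H", gene_specs=[{}] * 5)]
        low = [element_factory("L", stratum="low_U", gene_specs=[{}] * 5)]
        rows = enrichment_table(high, low, vocab, "HMRG")
        assert len(rows) == len(vocab.hmrg_cogs)
        assert all(r.p == 1.0 and r.q == 1.0 for r in rows)

    def test_counts_and_totals(self, element_factory, vocab):
        high = [element_factory("H", gene_specs=[{"cogs": ["COG2217"]}] * 3 + [{}] * 7)]
        low = [element_factory("L", stratum="low_U", gene_specs=[{}] * 10)]
        rows = {r.cog_id: r for r in enrichment_table(high, low, vocab, "HMRG")}
        r = rows["COG2217"]
        assert (r.count_high, r.count_low) == (3, 0)
        assert (r.total_cds_high, r.total_cds_low) == (10, 10)
        assert r.gene_name == "zntA"

    def test_exclude_cryptic_drops_elements(self, element_factory, vocab):
        high = [element_factory("H1", gene_specs=[{"cogs": ["COG2217"]}]),
                element_factory("H2", gene_specs=[{"cogs": ["COG2217"]}])]
        low = [element_factory("L1", stratum="low_U", gene_specs=[{}])]
        rows = {r.cog_id: r for r in enrichment_table(
            high, low, vocab, "HMRG", include_cryptic=False, cryptic_ids={"H2"})}
        assert rows["COG2217"].count_high == 1

    def test_empty_stratum_rejected(self, element_factory, vocab):
        with pytest.raises(ValueError, match="non-empty"):
            enrichment_table([], [element_factory("L", stratum="low_U")], vocab)


class TestAdjacency:
    def test_wrap_around_forced(self, element_factory, vocab):
        el = element_factory(gene_specs=[
            {"cogs": ["COG2217"]} if i in (1, 9) else {} for i in range(10)])
        assert adjacency_probability([el], vocab) == 1.0

    def test_distance_above_window_gives_zero(self, element_factory, vocab):
        el = element_factory(gene_specs=[
            {"cogs": ["COG2217"]} if i in (0, 6) else {} for i in range(12)])
        assert adjacency_probability([el], vocab) == 0.0

    def test_two_cogs_on_one_gene_not_self_adjacent(self, element_factory, vocab):
        el = element_factory(gene_specs=[
            {"cogs": ["COG2217", "COG0053"]}] + [{}] * 11)
        assert adjacency_probability([el], vocab) == 0.0

    def test_no_hmrg_distinct_from_zero(self, element_factory, vocab):
        assert adjacency_probability([element_factory(gene_specs=[{}])], vocab) is None

    def test_window_zero_always_zero(self, element_factory, vocab):
        el = element_factory(gene_specs=[
            {"cogs": ["COG2217"]}, {"cogs": ["COG0053"]}, {}])
        assert adjacency_probability([el], vocab, window=0) == 0.0

    def test_matches_pairwise_oracle_on_random_fixtures(self, element_factory, vocab):
        """500 random placements of 3 HMRGs on 40-gene circles."""
        rng = np.random.default_rng(17)
        hmrg = frozenset(vocab.hmrg_cogs)
        pool = sorted(vocab.hmrg_cogs)
        for rep in range(500):
            positions = rng.choice(40, size=3, replace=False)
            specs = []
            for i in range(40):
                if i in positions:
                    specs.append({"cogs": [pool[rng.integers(len(pool))]]})
                else:
                    specs.append({})
            el = element_factory(f"R{rep}", length_bp=40_000, gene_specs=specs)
            window = int(rng.integers(0, 8))
            assert adjacency_probability([el], vocab, window=window) == \
                adjacency_oracle([el], hmrg, window)


class TestCooccurrence:
    def test_pair_count_and_symmetry(self, element_factory, vocab):
        el = element_factory(gene_specs=[
            {"cogs": ["COG0789"]}, {"cogs": ["COG2059"]}, {}])
        mat = cooccurrence_matrix([el], vocab)
        assert mat.loc["merR", "chrA"] == 1 == mat.loc["chrA", "merR"]
        assert mat.loc["merR", "merR"] == 1
        assert mat.loc["merR", "zntA"] == 0
        assert (mat.values == mat.values.T).all()

    def test_no_shared_elements_zero(self, element_factory, vocab):
        els = [element_factory("A", gene_specs=[{"cogs": ["COG0789"]}]),
               element_factory("B", gene_specs=[{"cogs": ["COG2059"]}])]
        mat = cooccurrence_matrix(els, vocab)
        assert mat.loc["merR", "chrA"] == 0


class TestConjugation:
    def test_flag(self, element_factory, vocab):
        conj = element_factory(gene_specs=[{"cogs": ["COG3451"]}, {}])
        plain = element_factory(gene_specs=[{}, {}])
        assert conjugative_flag(conj, vocab) is True
        assert conjugative_flag(plain, vocab) is False

    def test_viral_element_rejected(self, element_factory, vocab):
        with pytest.raises(ValueError, match="viral"):
            conjugative_flag(element_factory(), vocab, is_viral=True)

    def test_all_hmrg_on_conjugative_fraction_one(self, element_factory, vocab):
        els = [
            element_factory("A", gene_specs=[
                {"cogs": ["COG2217"]}, {"cogs": ["COG3451"]}, {}]),
            element_factory("B", gene_specs=[{}] * 3),
        ]
        table, p, fraction = hmrg_conjugation_association(els, vocab)
        assert fraction == 1.0
        assert table == ((1, 0), (0, 1))

    def test_no_hmrg_fraction_undefined(self, element_factory, vocab):
        els = [element_factory("A", gene_specs=[{}])]
        _, _, fraction = hmrg_conjugation_association(els, vocab)
        assert fraction is None


class TestAmgs:
    def test_structural_gene_excluded_functional_reported(self, element_factory, vocab):
        el = element_factory("V1", gene_specs=[
            {"product": "major capsid protein"},
            {"product": "glutamine synthetase", "cogs": ["COG9001"]},
            {"product": "hypothetical protein"},
            {"product": "TerD family tellurium resistance protein", "cogs": ["COG2310"]},
        ])
        amgs = identify_amgs([el], vocab)
        products = [a["product"] for a in amgs]
        assert "major capsid protein" not in products
        assert "hypothetical protein" not in products
        assert "glutamine synthetase" in products
        terd = next(a for a in amgs if a["hmrg_flag"])
        assert terd["metals"] == ["Te"]


class TestSizeStats:
    def test_strict_threshold_and_welch(self, element_factory, vocab):
        els = [
            element_factory("H1", length_bp=20000, gene_specs=[{}]),
            element_factory("H2", length_bp=20001, gene_specs=[{}]),
            element_factory("L1", stratum="low_U", length_bp=20000, gene_specs=[{}]),
            element_factory("L2", stratum="low_U", length_bp=20001, gene_specs=[{}]),
        ]
        out = size_stats(els)
        assert out["per_stratum"]["high_U"]["count_gt_20kb"] == 1
        assert out["welch"]["t"] == 0.0
        assert out["welch"]["p"] == pytest.approx(1.0)
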