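"""Domain-type invariants and table/FASTA round trips."""

import pytest
from hypothesis import given, settings, strategies as st

from mobilome.io import (
    TableFormatError,
    load_vocabulary,
    read_annotation_table,
    read_evidence_table,
    read_fasta,
    write_annotation_table,
    write_evidence_table,
    write_fasta,
)
from mobilome.model import (
    CircularElement,
    EvidenceBundle,
    GeneFeature,
    Vocabulary,
    stratum_from_uranium,
)

HEADER = (
    "element_id\tsample_id\tstratum\telement_length\tgene_id\torf_index\t"
    "start\tend\tstrand\tcogs\tpfams\tdomains\ttax_phylum\ttax_class\tproduct"
)

EV_HEADER = (
    "element_id\tvirsorter_category\tplsdb_accession\tmash_distance\t"
    "mash_pvalue\tplsdb_host\tcrispr_hits\tphp_phylum\tlifestyle"
)


def _write(tmp_path, name, lines):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


class TestAnnotationTable:
    def test_groups_rows_into_ordered_elements(self, tmp_path):
        path = _write(tmp_path, "a.tsv", [
            "# comment",
            HEADER,
            "E1\tS1\thigh_U\t5000\tg1\t1\t2001\t4000\t-\tCOG2217,COG0745\t-\t-\t-\t-\t-",
            "E1\tS1\thigh_U\t5000\tg0\t0\t1\t2000\t+\t-\tPF01051\t-\tProteobacteria\tGammaproteobacteria\treplication protein",
        ])
        elements = read_annotation_table(path)
        assert len(elements) == 1
        el = elements[0]
        assert [g.orf_index for g in el.genes] == [0, 1]
        assert el.genes[1].cog_ids == {"COG2217", "COG0745"}
        assert el.genes[0].taxonomy == ("Proteobacteria", "Gammaproteobacteria")
        assert el.genes[1].taxonomy is None

    def test_duplicate_orf_index_rejected_with_row_number(self, tmp_path):
        path = _write(tmp_path, "a.tsv", [
            HEADER,
            "E1\tS1\thigh_U\t5000\tg0\t0\t1\t2000\t+\t-\t-\t-\t-\t-\t-",
            "E1\tS1\thigh_U\t5000\tg1\t0\t2001\t4000\t+\t-\t-\t-\t-\t-\t-",
        ])
        with pytest.raises(TableFormatError, match="3.*duplicate orf_index 0.*E1"):
            read_annotation_table(path)

    @pytest.mark.parametrize("bad_row,match", [
        ("E1\tS1\thigh_U\t5000\tg0\t0\tone\t2000\t+\t-\t-\t-\t-\t-\t-", "non-integer"),
        ("E1\tS1\tmid_U\t5000\tg0\t0\t1\t2000\t+\t-\t-\t-\t-\t-\t-", "unknown stratum"),
    ])
    def test_malformed_rows_rejected(self, tmp_path, bad_row, match):
        path = _write(tmp_path, "a.tsv", [HEADER, bad_row])
        with pytest.raises(TableFormatError, match=match):
            read_annotation_table(path)

    def test_round_trip_identity(self, tmp_path, element_factory):
        el = element_factory(gene_specs=[
            {"cogs": ["COG2217"], "taxonomy": ("Proteobacteria", "Betaproteobacteria"),
             "product": "zntA family protein"},
            {"pfams": ["PF01051"], "strand": "-"},
            {"domains": ["TIGR02224"], "product": "hypothetical protein"},
        ])
        path = tmp_path / "rt.tsv"
        write_annotation_table([el], path)
        (back,) = read_annotation_table(path)
        assert back == el


class TestEvidenceTable:
    def test_parse_contract(self, tmp_path):
        path = _write(tmp_path, "e.tsv", [
            EV_HEADER,
            "E1\t2\t-\t-\t-\t-\tRhodanobacter:0\tProteobacteria\ttemperate",
            "E2\t-\t-\t-\t-\t-\t-\t-\t-",
        ])
        bundles = read_evidence_table(path)
        assert bundles["E1"].virsorter_category == 2
        assert bundles["E1"].crispr_hits == [("Rhodanobacter", 0)]
        e2 = bundles["E2"]
        assert e2.virsorter_category is None and e2.plsdb_hit is None
        assert e2.crispr_hits == [] and e2.php_phylum is None and e2.lifestyle is None

    def test_mash_distance_out_of_range_rejected(self, tmp_path):
        path = _write(tmp_path, "e.tsv", [
            EV_HEADER,
            "E1\t-\tNZ_CP1\t1.5\t0.01\tAcinetobacter\t-\t-\t-",
        ])
        with pytest.raises(TableFormatError, match="mash_distance"):
            read_evidence_table(path)

    def test_round_trip_identity(self, tmp_path):
        bundles = [
            EvidenceBundle("E1", virsorter_category=4,
                           crispr_hits=[("Pseudomonas", 1), ("Bacillus", 3)],
                           php_phylum="Proteobacteria", lifestyle="virulent"),
            EvidenceBundle("E2", plsdb_hit=("NZ_CP1", 0.05, 0.001, "Sphingobium (Proteobacteria)")),
            EvidenceBundle("E3"),
        ]
        path = tmp_path / "rt.tsv"
        write_evidence_table(bundles, path)
        back = read_evidence_table(path)
        assert back == {b.element_id: b for b in bundles}


class TestVocabulary:
    def test_packaged_defaults_satisfy_invariants(self, vocab):
        assert vocab.hmrg_cogs["COG2217"] == {"Zn", "Cd", "Pb"}
        assert vocab.gene_name("COG2217") == "zntA"
        assert not (set(vocab.hmrg_cogs) | set(vocab.arg_cogs)) & set(vocab.conj_cogs)
        assert vocab.replication_pfams < vocab.mge_pfams

    def test_hmrg_conj_overlap_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            Vocabulary(hmrg_cogs={"COG0745": frozenset({"Cu"})},
                       conj_cogs=frozenset({"COG0745"}))

    def test_empty_conj_list_valid(self):
        v = Vocabulary(hmrg_cogs={"COG2217": frozenset({"Zn"})})
        assert v.conj_cogs == frozenset()


class TestFasta:
    def test_round_trip_and_uppercasing(self, tmp_path, element_factory):
        els = [
            element_factory("E1", length_bp=300, sequence="ACGT" * 75),
            element_factory("E2", length_bp=280, sequence="acgtn" * 56),
            element_factory("E3", length_bp=250, sequence=None),
        ]
        path = tmp_path / "x.fa"
        with pytest.warns(UserWarning, match="skipped 1"):
            skipped = write_fasta(els, path)
        assert skipped == 1
        seqs = read_fasta(path)
        assert seqs == {"E1": "ACGT" * 75, "E2": "ACGTN" * 56}
        assert max(len(line) for line in path.read_text().splitlines()) <= 70

    def test_id_collision_rejected(self, tmp_path, element_factory):
        els = [element_factory("E1", sequence=None), element_factory("E1", sequence=None)]
        with pytest.raises(ValueError, match="duplicate"):
            write_fasta(els, tmp_path / "x.fa")


class TestDomainTypes:
    def test_orf_indices_must_be_consecutive(self):
        genes = [GeneFeature("g0", 0, 1, 100, "+"), GeneFeature("g2", 2, 101, 200, "+")]
        with pytest.raises(ValueError, match="consecutive"):
            CircularElement("E1", "S1", "high_U", 1000, genes=genes)

    def test_sequence_length_must_match(self):
        with pytest.raises(ValueError, match="length"):
            CircularElement("E1", "S1", "high_U", 1000, sequence="ACGT")

    @pytest.mark.parametrize("u,expected", [
        (0.2, "high_U"), (0.05, "low_U"), (0.126, "low_U"),
    ])
    def test_uranium_stratum_threshold(self, u, expected):
        assert stratum_from_uranium(u) == expected


@settings(max_examples=25, deadline=None)
@given(st.lists(
    st.tuples(
        st.integers(1, 6),  # number of genes
        st.sampled_from(["high_U", "low_U"]),
        st.sets(st.sampled_from(["COG2217", "COG0053", "COG9001"]), max_size=2),
    ),
    min_size=1, max_size=5,
))
def test_annotation_round_trip_property(tmp_path_factory, specs):
    """read(write(X)) == X for randomly composed valid element sets."""
    elements = []
    for k, (n_genes, stratum, cogs) in enumerate(specs):
        genes = [
            GeneFeature(f"E{k}_g{i}", i, i * 100 + 1, (i + 1) * 100, "+",
                        cog_ids=frozenset(cogs))
            for i in range(n_genes)
        ]
        elements.append(CircularElement(f"E{k}", "S", stratum, 200 + n_genes * 100, genes=genes))
    path = tmp_path_factory.mktemp("rt") / "a.tsv"
    write_annotation_table(elements, path)
    assert read_annotation_table(path) == elements
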