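import pytest

from mobilome.io import load_vocabulary
from mobilome.model import CircularElement, GeneFeature


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


def make_element(
    element_id="E1",
    stratum="high_U",
    length_bp=10000,
    gene_specs=(),
    sequence=None,
    sample_id="S1",
):
    """Build a CircularElement from light-weight per-gene spec dicts."""
    genes = []
    n = len(gene_specs)
    pitch = max(length_bp // max(n, 1), 1)
    for i, spec in enumerate(gene_specs):
        genes.append(GeneFeature(
            gene_id=spec.get("gene_id", f"{element_id}_g{i}"),
            orf_index=i,
            start=spec.get("start", i * pitch + 1),
            end=spec.get("end", min((i + 1) * pitch, length_bp)),
            strand=spec.get("strand", "+"),
            cog_ids=frozenset(spec.get("cogs", ())),
            pfam_ids=frozenset(spec.get("pfams", ())),
            domain_ids=frozenset(spec.get("domains", ())),
            taxonomy=spec.get("taxonomy"),
            product=spec.get("product", ""),
        ))
    return CircularElement(
        element_id=element_id, sample_id=sample_id, stratum=stratum,
        length_bp=length_bp, genes=genes, sequence=sequence,
    )


@pytest.fixture
def element_factory():
    return make_element
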