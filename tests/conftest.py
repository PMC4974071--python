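import pytest

from denovotest.genes import TrinucleotideRateTable, build_gene_model
from denovotest.phenosim import Ontology, ProbandAnnotations


@pytest.fixture
def toy_gene():
    """ATG AAA TAG — one exon, flanks supplied so every site has context."""
    return build_gene_model(
        "toy", [(0, 9)], "ATGAAATAG", flank_5="C", flank_3="C"
    )


@pytest.fixture
def uniform_rates():
    return TrinucleotideRateTable.uniform(1e-9)


@pytest.fixture
def diamond_ontology():
    """Seven terms; leaf L has two is_a paths to the root (a diamond)."""
    edges = [
        ("A", "root"), ("B", "root"),
        ("C", "A"), ("D", "A"), ("E", "B"),
        ("L", "C"), ("L", "E"),
    ]
    return Ontology.from_edges(edges)


@pytest.fixture
def small_cohort(diamond_ontology):
    """Six annotated probands over the diamond ontology."""
    ann = {
        "p1": {"L"},
        "p2": {"L", "D"},
        "p3": {"C"},
        "p4": {"D"},
        "p5": {"E"},
        "p6": {"B"},
    }
    return ProbandAnnotations(annotations=ann, ontology=diamond_ontology)
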