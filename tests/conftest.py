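import pytest

from phylomekit.treeio import parse_newick, parse_species_tree


@pytest.fixture
def primate_species_tree():
    return parse_species_tree(
        "(((HUMAN,PANTR)Primates,MOUSE)Mammalia,YEAST)Eukaryota;"
    )


@pytest.fixture
def two_by_two_tree():
    """Root duplication over two speciated (HUMAN, MOUSE) cherries."""
    return parse_newick("((H1_HUMAN,M1_MOUSE),(H2_HUMAN,M2_MOUSE));")


@pytest.fixture
def simple_species_tree():
    return parse_species_tree("((HUMAN,MOUSE),YEAST);")
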