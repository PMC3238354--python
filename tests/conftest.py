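import pytest

from enrichkit import GeneSet, GeneSetCollection, PairSet, parse_gene_info


@pytest.fixture
def apoe_map():
    """Minimal human symbol map: APOE plus an ambiguous synonym X."""
    lines = [
        "#tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\n",
        "9606\t348\tAPOE\t-\tAD2|APO-E\n",
        "9606\t10\tGENA\t-\tX\n",
        "9606\t20\tGENB\t-\tX\n",
        "10090\t11816\tApoe\t-\tAD-2\n",
    ]
    return parse_gene_info(lines, species=9606)


@pytest.fixture
def toy_collection():
    """Background {1..20}; set A = {1..10}, set B = {11..14}."""
    return GeneSetCollection(
        name="toy",
        species=9606,
        sets=[
            GeneSet("pathA", "first ten genes", frozenset(range(1, 11))),
            GeneSet("pathB", "four genes", frozenset(range(11, 15))),
        ],
    )


@pytest.fixture
def chain_pairs():
    """Path graph 1-2-3-4 as an interaction pair set."""
    return PairSet(species=9606, pairs={(1, 2), (2, 3), (3, 4)}, source_label="chain")
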