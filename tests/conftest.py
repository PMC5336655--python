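import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from setrank import GeneSet, GeneSetCollection, RankedGeneList


@pytest.fixture
def small_collection():
    return GeneSetCollection([
        GeneSet("A", "set A", "GOBP", frozenset({"g1", "g2", "g3"})),
        GeneSet("B", "set B", "KEGG", frozenset({"g2", "g3", "g4", "g5"})),
        GeneSet("C", "set C", "GOBP", frozenset({"g6", "g7", "g8"})),
    ])


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "SET1\tfirst set\tg1\tg2\tg3\n"
        "SET2\tsecond set\tg2\tg3\tg4\tg5\n"
        "SET3\tthird set\tg1\tg1\tg6\tg7\n"  # duplicated gene collapses
    )
    return path


def random_ranked_list(rng, l):
    genes = np.array([f"g{k}" for k in range(l)], dtype=object)
    return RankedGeneList(genes, rng.uniform(0, 1, l))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
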