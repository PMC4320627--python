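import numpy as np
import pytest

from chipregulon.formats import GeneRecord, GenomeModel


@pytest.fixture
def toy_genome() -> GenomeModel:
    """Hand-built 20 kb genome: forward/reverse genes, a divergent pair, an operon.

    Layout (0-based half-open):
      g1 +  [1000, 2000)   tsc 1000
      g2 -  [3000, 4000)   tsc 3999
      g3 -  [4300, 4800)   tsc 4799   } divergent pair around ~4800..5000
      g4 +  [5000, 6000)   tsc 5000   }
      g5 +  [8000, 9000)   tsc 8000   operon op1 pos 1
      g6 +  [9050, 10000)  tsc 9050   operon op1 pos 2
      g7 +  [10040, 11000) tsc 10040  operon op1 pos 3
      g8 -  [15000, 16000) tsc 15999
    """
    genes = [
        GeneRecord("g1", "+", 1000, 2000, category="catA"),
        GeneRecord("g2", "-", 3000, 4000, category="catA"),
        GeneRecord("g3", "-", 4300, 4800, category="catB"),
        GeneRecord("g4", "+", 5000, 6000, category="catB"),
        GeneRecord("g5", "+", 8000, 9000, category="catB",
                   operon_id="op1", operon_position=1),
        GeneRecord("g6", "+", 9050, 10000, category="catC",
                   operon_id="op1", operon_position=2),
        GeneRecord("g7", "+", 10040, 11000, category="catC",
                   operon_id="op1", operon_position=3),
        GeneRecord("g8", "-", 15000, 16000, category="catC"),
    ]
    return GenomeModel("chr", 20000, genes)


@pytest.fixture(scope="session")
def dataset():
    """A mid-size synthetic world shared by the slower closed-loop tests."""
    from chipregulon.synthetic import make_dataset

    return make_dataset(seed=7, n_genes=400, n_sites=80,
                        n_false_per_replicate=25)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
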