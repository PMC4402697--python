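import numpy as np
import pytest

from pigs.graph import ProbabilisticIBDGraph


@pytest.fixture
def worked_graph() -> ProbabilisticIBDGraph:
    """Three haplotypes where two strong edges imply the weak third."""
    return ProbabilisticIBDGraph(
        [1, 2, 3], {(1, 2): 0.9, (1, 3): 0.9, (2, 3): 0.1}
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150318)
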