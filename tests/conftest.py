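import numpy as np
import pytest

from .oracles import ds_trees_by_relation


@pytest.fixture(scope="session")
def ds_tables():
    """All DS-trees grouped by induced ortholog set, per leaf count (canonical labels)."""
    return {n: ds_trees_by_relation([f"g{i}" for i in range(n)]) for n in range(1, 6)}


@pytest.fixture
def rng():
    return np.random.default_rng(20140)
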