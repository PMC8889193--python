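import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from oximap.simulate import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def small_genome():
    """A 600-kb single-scaffold genome with two planted clusters."""
    cfg = SyntheticConfig(seed=11, n_scaffolds=1, scaffold_len=600_000, n_te_clusters=2)
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_genome():
    """The default 2-Mb, two-scaffold genome with three planted clusters."""
    return simulate(SyntheticConfig(seed=7))
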