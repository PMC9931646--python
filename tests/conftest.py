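import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gabc.scoring import ScoringConfig
from gabc.synth import make_toy_locus


@pytest.fixture(scope="session")
def toy_locus():
    """A default toy locus: 6 enhancers, 3 genes x 2 TSSs, 2 conditions."""
    return make_toy_locus(seed=7)


@pytest.fixture(scope="session")
def toy_locus_on_disk(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("locus")
    return make_toy_locus(seed=7, outdir=outdir)


@pytest.fixture()
def gabc_config():
    return ScoringConfig(use_adapted_activity=True, use_all_tss=True)


@pytest.fixture()
def abc_config():
    return ScoringConfig(use_adapted_activity=False, use_all_tss=False)
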