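import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from tas3scan.config import default_config
from tas3scan.seqs import revcomp


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def mir390(cfg):
    return cfg.guide_variants("miR390")[0]


@pytest.fixture(scope="session")
def sim_defaults(cfg):
    return {
        "guide390": cfg.guide_variants("miR390")[0],
        "guide156": cfg.guide_variants("miR156")[0],
        "guide529": cfg.guide_variants("miR529")[0],
        "tasi_refs": cfg.tasi_refs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20130924)


def make_perfect_hairpin(stem5: str, loop: str) -> str:
    """stem5 + loop + revcomp(stem5): folds into a perfect helix."""
    return stem5 + loop + revcomp(stem5)
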