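import numpy as np
import pytest

from chromocat.model import GenomeBuild


@pytest.fixture
def genome():
    """Small two-chromosome build with centromeres."""
    return GenomeBuild(
        ("chr1", "chr5", "chr8", "chr9"),
        {"chr1": 200_000_000, "chr5": 180_000_000, "chr8": 150_000_000, "chr9": 140_000_000},
        {"chr1": (90_000_000, 92_000_000), "chr5": (45_000_000, 47_000_000),
         "chr8": (44_000_000, 46_000_000), "chr9": (47_000_000, 49_000_000)},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
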