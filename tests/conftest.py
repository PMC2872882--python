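import numpy as np
import pytest

from chiapet.linker import LinkerSpec
from chiapet.mapping import MapStatus, TagAlignment, make_mapped_pet


@pytest.fixture
def spec() -> LinkerSpec:
    return LinkerSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def mk_pet(
    pid="p0",
    chrom1="chr1",
    pos1=100,
    strand1="+",
    chrom2="chr1",
    pos2=600,
    strand2="-",
):
    """Convenience constructor for a uniquely mapped PET (canonical head/tail)."""
    a1 = TagAlignment(MapStatus.UNIQUE, chrom1, pos1, strand1, 0)
    a2 = TagAlignment(MapStatus.UNIQUE, chrom2, pos2, strand2, 0)
    return make_mapped_pet(pid, a1, a2)


@pytest.fixture
def make_pet():
    return mk_pet
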