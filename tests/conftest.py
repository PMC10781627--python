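import numpy as np
import pytest

from ibdstruct import IBDSegment, default_map, uniform_map


@pytest.fixture(scope="session")
def unimap():
    """One uniform chromosome: 100 Mb / 100 cM (1 cM per Mb)."""
    return uniform_map(1, 100_000_000, 100.0)


@pytest.fixture(scope="session")
def map22():
    return default_map()


@pytest.fixture
def seg_factory(unimap):
    """Segment builder on the uniform map with auto-computed cM length."""

    def make(a="s1", b="s2", chrom="1", start=0, end=10_000_000, lod=10.0,
             gmap=unimap, length_cm=None):
        return IBDSegment(
            sample_a=a, sample_b=b, chromosome=chrom, start_bp=start, end_bp=end,
            length_cm=(gmap.segment_cm(chrom, start, end)
                       if length_cm is None else length_cm),
            lod=lod,
        )

    return make
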