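import pytest

from chimseq.io_counts import BASES, BaseCount, GenomicLocus, SNPMarker


def make_bc(ref="A", chrom="1", pos=100, **counts) -> BaseCount:
    full = {b: 0 for b in BASES}
    full.update(counts)
    return BaseCount(GenomicLocus(chrom, pos), ref, full)


@pytest.fixture
def ag_marker() -> SNPMarker:
    """A biallelic A/G panel SNP with mid-range population heterozygosity."""
    return SNPMarker(GenomicLocus("1", 100), "A", "G", het_freq=0.4, id="rs_test")
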