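import pytest
from hypothesis import settings

from somaticstack.model import BreakendPair, SampleCounts, SmallVariant

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def make_variant():
    """Factory for small variants with sensible count defaults."""

    def _make(chrom="chr1", pos=100, ref="A", alt="G", callers=("strelka2",),
              tumor=(40, 60), normal=(100, 0), **kwargs):
        v = SmallVariant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         caller_support=set(callers), **kwargs)
        if tumor is not None:
            v.tumor_counts = SampleCounts(tumor[0], tumor[1],
                                          tumor[0] + tumor[1], source="PILEUP")
        if normal is not None:
            v.normal_counts = SampleCounts(normal[0], normal[1],
                                           normal[0] + normal[1], source="PILEUP")
        return v

    return _make


@pytest.fixture
def make_sv():
    """Factory for breakend pairs; defaults to a 10 kb deletion."""

    def _make(chrom1="chr1", start1=10_000, chrom2=None, start2=20_000,
              svtype="DEL", strands=None, callers=("manta",), ci=1, **kwargs):
        strands = strands or {"DEL": ("+", "-"), "DUP": ("-", "+"),
                              "INV": ("+", "+"), "INS": ("+", "-"),
                              "TRA": ("+", "-")}[svtype]
        return BreakendPair(
            chrom1=chrom1, start1=start1, end1=start1 + ci,
            chrom2=chrom2 or chrom1, start2=start2, end2=start2 + ci,
            strand1=strands[0], strand2=strands[1], svtype=svtype,
            caller_support=set(callers), **kwargs)

    return _make
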