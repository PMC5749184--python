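import numpy as np
import pytest

from scduoqc.io_formats import (
    BinnedCounts,
    FractionType,
    GenomeBins,
    ReadAnnotation,
    ReadRecord,
    SAM_FLAG_DUPLICATE,
    SAM_FLAG_PROPER_PAIR,
    SAM_FLAG_UNMAPPED,
)


@pytest.fixture
def small_bins() -> GenomeBins:
    return GenomeBins.uniform({"chr1": 4_000_000}, bin_size=1_000_000)


@pytest.fixture
def make_counts(small_bins):
    def _make(counts, **kw):
        n = len(counts)
        bins = (
            small_bins
            if n == 4
            else GenomeBins.uniform({"chr1": n * 1_000_000}, bin_size=1_000_000)
        )
        return BinnedCounts(bins, np.asarray(counts), **kw)

    return _make


def make_read(
    mapped=True,
    duplicate=False,
    proper=False,
    chrom="chr1",
    mate_chrom=None,
    annotation=ReadAnnotation.INTERGENIC,
    pos=100,
):
    flags = 0
    if not mapped:
        flags |= SAM_FLAG_UNMAPPED
        annotation = ReadAnnotation.UNALIGNED
    if duplicate:
        flags |= SAM_FLAG_DUPLICATE
    if proper:
        flags |= SAM_FLAG_PROPER_PAIR
    return ReadRecord(
        flags=flags,
        chrom=chrom,
        mate_chrom=mate_chrom if mate_chrom is not None else chrom,
        pos=pos if mapped else -1,
        annotation=annotation,
    )


@pytest.fixture
def toy_sam(tmp_path):
    """10-record toy SAM: 8 mapped (2 of them mate on chr2), 2 unmapped."""
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        "@SQ\tSN:chr1\tLN:1000000",
        "@SQ\tSN:chr2\tLN:1000000",
    ]
    for i in range(6):
        lines.append(f"r{i}\t2\tchr1\t{100 + i}\t60\t50M\t=\t{200 + i}\t0\t*\t*")
    for i in range(6, 8):
        lines.append(f"r{i}\t0\tchr1\t{100 + i}\t60\t50M\tchr2\t{200 + i}\t0\t*\t*")
    for i in range(8, 10):
        lines.append(f"r{i}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*")
    path = tmp_path / "toy.sam"
    path.write_text("\n".join(lines) + "\n")
    return path
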