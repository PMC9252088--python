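"""Shared fixtures: tiny genomes, SAM fixtures built programmatically."""

import numpy as np
import pysam
import pytest

from tagpeaks import ChromSizes, FragmentSet

SAM_HEADER = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": 100_000}]}


@pytest.fixture
def chrom_sizes() -> ChromSizes:
    return ChromSizes({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def chrom_sizes_file(tmp_path):
    path = tmp_path / "genome.chrom.sizes"
    path.write_text("chr1\t100000\nchr2\t50000\n")
    return path


def make_fragment_set(intervals: list[tuple[str, int, int]]) -> FragmentSet:
    return FragmentSet.from_fragments(intervals)


def write_sam(path, reads):
    """Write a SAM file from (qname, flag, pos0, cigar, pnext0, tlen) tuples."""
    with pysam.AlignmentFile(str(path), "w", header=SAM_HEADER) as out:
        for qname, flag, pos, cigar, pnext, tlen in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.next_reference_id = 0 if pnext >= 0 else -1
            a.next_reference_start = pnext
            a.template_length = tlen
            out.write(a)
    return path


@pytest.fixture
def proper_pair_sam(tmp_path):
    """One properly paired fragment: mate A [100,150), mate B [200,260)."""
    reads = [
        # flag 99 = paired, proper, mate reverse, first in pair
        ("pair1", 99, 100, "50M", 200, 160),
        # flag 147 = paired, proper, reverse, second in pair
        ("pair1", 147, 200, "60M", 100, -160),
    ]
    return write_sam(tmp_path / "pair.sam", reads)


def brute_force_bin_counts(bins, fragments):
    """Double-loop oracle: count fragments overlapping each bin by >= 1 bp."""
    counts = []
    for b_start, b_end in bins:
        n = 0
        for f_start, f_end in fragments:
            if f_start < b_end and f_end > b_start:
                n += 1
        counts.append(n)
    return np.array(counts)
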