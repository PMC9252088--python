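"""Reading and writing of fragment data and genomic intervals.

This module handles the plumbing around the peak caller: chromosome-sizes
files (UCSC ``chrom.sizes`` format), paired-end alignment files (BAM/SAM/CRAM
via :mod:`pysam`), plain interval files (BED3/BEDPE) holding pre-extracted
fragments, scored interval files (narrowPeak/broadPeak-style), blacklist
exclusion, and BED serialization of called peaks.

Coordinates are 0-based half-open everywhere, matching the BED standard.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Iterator, Mapping
from typing import NamedTuple

import numpy as np
import pysam
from intervaltree import IntervalTree

__all__ = [
    "FileFormatError",
    "Fragment",
    "ScoredInterval",
    "ChromSizes",
    "FragmentSet",
    "read_chrom_sizes",
    "read_fragments",
    "read_bed_intervals",
    "read_scored_intervals",
    "exclude_blacklist",
    "write_bed",
]


class FileFormatError(ValueError):
    """Raised when an input file violates its format contract."""


class Fragment(NamedTuple):
    """A sequenced paired-end fragment as a half-open genomic interval."""

    chrom: str
    start: int
    end: int


class ScoredInterval(NamedTuple):
    """A genomic interval with a context-dependent non-negative score.

    For ChIP-seq "standard" peak sets the score is a -log10 p-value; for
    ranked consensus peaks it is a fragment count.
    """

    chrom: str
    start: int
    end: int
    score: float


class ChromSizes(Mapping[str, int]):
    """Ordered mapping of chromosome name to length in bp.

    Iteration order is the order of first insertion (file order), which also
    defines the sort order of BED output.
    """

    def __init__(self, items: Iterable[tuple[str, int]] | Mapping[str, int]):
        if isinstance(items, Mapping):
            items = items.items()
        self._sizes: dict[str, int] = {}
        for name, length in items:
            name = str(name)
            length = int(length)
            if name in self._sizes:
                raise FileFormatError(f"duplicate chromosome name: {name!r}")
            if length <= 0:
                raise FileFormatError(
                    f"non-positive length for chromosome {name!r}: {length}"
                )
            self._sizes[name] = length
        if not self._sizes:
            raise FileFormatError("chromosome sizes are empty")

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    @property
    def names(self) -> list[str]:
        return list(self._sizes)

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ChromSizes({self._sizes!r})"


def read_chrom_sizes(path: str | os.PathLike) -> ChromSizes:
    """Parse a two-column ``name<TAB>length`` chromosome-sizes file.

    Raises
    ------
    FileFormatError
        On a malformed line, a non-positive length, or a duplicate name;
        the error message names the offending line.
    """
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise FileFormatError(f"{path}: malformed line {lineno}: {line!r}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise FileFormatError(
                    f"{path}: non-integer length on line {lineno}: {line!r}"
                ) from None
            if length <= 0:
                raise FileFormatError(
                    f"{path}: non-positive length on line {lineno}: {line!r}"
                )
            if name in seen:
                raise FileFormatError(
                    f"{path}: duplicate chromosome on line {lineno}: {name!r}"
                )
            seen.add(name)
            entries.append((name, length))
    if not entries:
        raise FileFormatError(f"{path}: no chromosome entries found")
    return ChromSizes(entries)


class FragmentSet:
    """Fragments for one sample, stored per-chromosome as interval arrays.

    Parameters
    ----------
    intervals
        Mapping of chromosome name to an ``(n, 2)`` integer array of
        half-open ``[start, end)`` intervals. Arrays are copied and sorted
        by start coordinate.

    Notes
    -----
    ``total`` is the library depth used for CPM normalization and as the
    number of trials of the genome-wide binomial null; it always equals the
    number of fragments held.
    """

    def __init__(self, intervals: Mapping[str, np.ndarray]):
        self._intervals: dict[str, np.ndarray] = {}
        for chrom, arr in intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and np.any(arr[:, 0] >= arr[:, 1]):
                bad = arr[arr[:, 0] >= arr[:, 1]][0]
                raise ValueError(
                    f"invalid fragment on {chrom}: [{bad[0]}, {bad[1]})"
                )
            if arr.size and np.any(arr[:, 0] < 0):
                raise ValueError(f"negative fragment start on {chrom}")
            order = np.argsort(arr[:, 0], kind="stable")
            self._intervals[str(chrom)] = arr[order]

    @classmethod
    def from_fragments(cls, fragments: Iterable[tuple[str, int, int]]) -> "FragmentSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in fragments:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        return cls(
            {
                c: np.array(v, dtype=np.int64).reshape(-1, 2)
                for c, v in by_chrom.items()
            }
        )

    @property
    def total(self) -> int:
        """Number of fragments (library depth)."""
        return sum(arr.shape[0] for arr in self._intervals.values())

    @property
    def chroms(self) -> list[str]:
        return list(self._intervals)

    def intervals(self, chrom: str) -> np.ndarray:
        """``(n, 2)`` start-sorted interval array for one chromosome."""
        return self._intervals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __len__(self) -> int:
        return self.total

    def __iter__(self) -> Iterator[Fragment]:
        for chrom in self._intervals:
            for start, end in self._intervals[chrom]:
                yield Fragment(chrom, int(start), int(end))

    def count_overlaps(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Number of fragments overlapping each query interval by >= 1 bp.

        Uses sorted starts/ends: a fragment overlaps ``[s, e)`` unless its
        start >= e or its end <= s, and those two exclusion sets are disjoint.
        """
        arr = self.intervals(chrom)
        n = arr.shape[0]
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if n == 0:
            return np.zeros(starts.shape, dtype=np.int64)
        frag_starts = arr[:, 0]  # already sorted
        frag_ends = np.sort(arr[:, 1])
        n_start_ge = n - np.searchsorted(frag_starts, ends, side="left")
        n_end_le = np.searchsorted(frag_ends, starts, side="right")
        return n - n_start_ge - n_end_le

    def validate_against(self, chrom_sizes: ChromSizes) -> None:
        """Hard-error if any fragment lies on an unknown chromosome or
        extends past its chromosome end."""
        for chrom, arr in self._intervals.items():
            if arr.shape[0] == 0:
                continue
            if chrom not in chrom_sizes:
                raise ValueError(f"fragment on unknown chromosome: {chrom!r}")
            if int(arr[:, 1].max()) > chrom_sizes[chrom]:
                raise ValueError(
                    f"fragment exceeds length of chromosome {chrom!r}"
                )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FragmentSet(total={self.total}, chroms={self.chroms})"


def _read_fragments_alignment(
    path: str | os.PathLike, min_mapq: int, tlen_bounds: tuple[int, int]
) -> FragmentSet:
    lo, hi = tlen_bounds
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    n_reads = 0
    n_paired = 0
    with pysam.AlignmentFile(os.fspath(path), require_index=False) as bam:
        for read in bam:
            if read.is_unmapped:
                continue
            n_reads += 1
            if not read.is_paired:
                continue
            n_paired += 1
            if not read.is_proper_pair:
                continue
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            tlen = read.template_length
            # Count each pair once, from its leftmost mate; the template
            # length then spans leftmost mate start to rightmost mate end.
            if tlen <= 0:
                continue
            if not (lo <= tlen <= hi):
                continue
            start = read.reference_start
            by_chrom.setdefault(read.reference_name, []).append((start, start + tlen))
    if n_reads > 0 and n_paired == 0:
        raise FileFormatError(
            f"{path}: alignment file contains only single-end reads; "
            "extract fragments to BED/BEDPE and use interval input instead"
        )
    return FragmentSet.from_fragments(
        (c, s, e) for c, pairs in by_chrom.items() for s, e in pairs
    )


def _read_fragments_bed(path: str | os.PathLike) -> FragmentSet:
    frags: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FileFormatError(f"{path}: malformed BED line {lineno}")
            try:
                frags.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError:
                raise FileFormatError(
                    f"{path}: non-integer coordinate on line {lineno}"
                ) from None
    return FragmentSet.from_fragments(frags)


def _read_fragments_bedpe(path: str | os.PathLike) -> FragmentSet:
    frags: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FileFormatError(f"{path}: malformed BEDPE line {lineno}")
            c1, s1, e1, c2, s2, e2 = fields[:6]
            if c1 != c2:
                raise FileFormatError(
                    f"{path}: inter-chromosomal pair on line {lineno}"
                )
            try:
                start = min(int(s1), int(s2))
                end = max(int(e1), int(e2))
            except ValueError:
                raise FileFormatError(
                    f"{path}: non-integer coordinate on line {lineno}"
                ) from None
            frags.append((c1, start, end))
    return FragmentSet.from_fragments(frags)


_ALIGNMENT_EXTS = {".bam", ".sam", ".cram"}


def read_fragments(
    path: str | os.PathLike,
    min_mapq: int = 0,
    tlen_bounds: tuple[int, int] = (10, 700),
) -> FragmentSet:
    """Read paired-end fragments from an alignment or interval file.

    Alignment input (``.bam``/``.sam``/``.cram``): one fragment per properly
    paired read pair, spanning leftmost mate start to rightmost mate end,
    counted once per pair. Secondary, supplementary, and duplicate-flagged
    alignments are skipped; ``min_mapq`` and ``tlen_bounds`` (template-length
    window, mirroring typical aligner insert bounds) apply here only.

    Interval input: BED3+ (``.bed``, one fragment per row, columns 1-3) or
    BEDPE (``.bedpe``, fragment spans both mates).
    """
    ext = os.path.splitext(os.fspath(path))[1].lower()
    if ext in _ALIGNMENT_EXTS:
        return _read_fragments_alignment(path, min_mapq, tlen_bounds)
    if ext == ".bedpe":
        return _read_fragments_bedpe(path)
    return _read_fragments_bed(path)


def read_bed_intervals(path: str | os.PathLike) -> list[Fragment]:
    """Read a BED3+ file as a list of plain intervals."""
    out: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FileFormatError(f"{path}: malformed BED line {lineno}")
            out.append(Fragment(fields[0], int(fields[1]), int(fields[2])))
    return out


def read_scored_intervals(path: str | os.PathLike) -> list[ScoredInterval]:
    """Read scored intervals from narrowPeak/broadPeak or BED5 files.

    For files with >= 8 columns the 8th column is taken as the score
    (the -log10 p-value slot of the narrowPeak/broadPeak standard);
    otherwise the 5th (BED score) or 4th column is used.
    """
    out: list[ScoredInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FileFormatError(
                    f"{path}: expected a score column on line {lineno}"
                )
            if len(fields) >= 8:
                score_field = fields[7]
            elif len(fields) >= 5:
                score_field = fields[4]
            else:
                score_field = fields[3]
            try:
                score = float(score_field)
            except ValueError:
                raise FileFormatError(
                    f"{path}: non-numeric score on line {lineno}: {score_field!r}"
                ) from None
            if score < 0:
                raise FileFormatError(
                    f"{path}: negative score on line {lineno}"
                )
            out.append(
                ScoredInterval(fields[0], int(fields[1]), int(fields[2]), score)
            )
    return out


def _blacklist_trees(
    blacklist: Iterable[tuple[str, int, int]],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for item in blacklist:
        chrom, start, end = item[0], int(item[1]), int(item[2])
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def exclude_blacklist(items, blacklist):
    """Remove items overlapping (>= 1 bp) any blacklist interval.

    ``items`` may be a :class:`FragmentSet` (a filtered FragmentSet is
    returned) or an iterable of interval tuples/namedtuples (a list of the
    surviving items, in input order, is returned). Half-open adjacency is
    not overlap. An empty blacklist is the identity.
    """
    trees = _blacklist_trees(blacklist)
    if isinstance(items, FragmentSet):
        kept: dict[str, np.ndarray] = {}
        for chrom in items.chroms:
            arr = items.intervals(chrom)
            tree = trees.get(chrom)
            if tree is None or arr.shape[0] == 0:
                kept[chrom] = arr
                continue
            mask = np.fromiter(
                (not tree.overlaps(int(s), int(e)) for s, e in arr),
                dtype=bool,
                count=arr.shape[0],
            )
            kept[chrom] = arr[mask]
        return FragmentSet(kept)
    out = []
    for item in items:
        chrom, start, end = item[0], int(item[1]), int(item[2])
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(start, end):
            continue
        out.append(item)
    return out


def write_bed(
    intervals,
    path: str | os.PathLike,
    chrom_order: Iterable[str] | None = None,
) -> None:
    """Write intervals as tab-separated BED, sorted by chromosome then start.

    ``intervals`` is an iterable of tuples whose first three elements are
    ``(chrom, start, end)``; any further elements (name, score, ...) are
    written as extra columns. ``chrom_order`` (e.g. ``ChromSizes`` names)
    fixes the chromosome sort order; chromosomes not listed sort after the
    listed ones, lexicographically.
    """
    rows = [tuple(item) for item in intervals]
    order_index: dict[str, int] = {}
    if chrom_order is not None:
        order_index = {name: i for i, name in enumerate(chrom_order)}
    big = len(order_index)

    def key(row):
        return (order_index.get(row[0], big), row[0], int(row[1]), int(row[2]))

    rows.sort(key=key)
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
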