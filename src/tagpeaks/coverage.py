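"""Sliding-bin coverage: bin grid, fragment counting, CPM, control scaling.

The genome is partitioned into bins of width ``step`` whose starts lie on a
grid spaced ``slide`` bp apart (bins overlap when ``slide < step``). Raw
per-bin counts are the number of fragments overlapping each bin by at least
1 bp, so one fragment may increment several overlapping bins. Counts are
normalized to counts per million (CPM) using the library fragment total, and
optionally scaled against a negative control (IgG/input) with a piecewise
formula that zeroes bins the control dominates and down-weights the rest by
the control:sample CPM ratio.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ChromSizes, FragmentSet

__all__ = ["BinGrid", "BinCounts", "make_bins", "count_fragments",
           "scale_to_control", "write_bedgraph"]


@dataclass(frozen=True)
class BinGrid:
    """Sliding-window partition of the genome.

    Bin starts on each chromosome are ``0, slide, 2*slide, ...`` up to (but
    excluding) the chromosome length; each bin ends at
    ``min(start + step, chrom_length)``, so trailing bins are truncated and
    every bin is non-empty.
    """

    chrom_sizes: ChromSizes
    step: int
    slide: int

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if not (0 < self.slide <= self.step):
            raise ValueError(
                f"slide must satisfy 0 < slide <= step, got slide={self.slide} "
                f"step={self.step}"
            )

    def n_bins(self, chrom: str) -> int:
        length = self.chrom_sizes[chrom]
        return -(-length // self.slide)  # ceil: starts strictly below length

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_sizes)

    @property
    def offsets(self) -> dict[str, int]:
        """Flat-array offset of each chromosome's first bin."""
        out: dict[str, int] = {}
        acc = 0
        for chrom in self.chrom_sizes:
            out[chrom] = acc
            acc += self.n_bins(chrom)
        return out

    def starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.slide

    def ends(self, chrom: str) -> np.ndarray:
        return np.minimum(self.starts(chrom) + self.step, self.chrom_sizes[chrom])

    def locate(self, flat_index: np.ndarray) -> pd.DataFrame:
        """Map flat bin indices back to (chrom, start, end) records."""
        flat_index = np.asarray(flat_index, dtype=np.int64)
        chroms = np.empty(flat_index.shape, dtype=object)
        starts = np.empty(flat_index.shape, dtype=np.int64)
        ends = np.empty(flat_index.shape, dtype=np.int64)
        for chrom, off in self.offsets.items():
            n = self.n_bins(chrom)
            mask = (flat_index >= off) & (flat_index < off + n)
            if not mask.any():
                continue
            local = flat_index[mask] - off
            chroms[mask] = chrom
            starts[mask] = local * self.slide
            ends[mask] = np.minimum(starts[mask] + self.step,
                                    self.chrom_sizes[chrom])
        return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})

    def same_grid(self, other: "BinGrid") -> bool:
        return (
            self.step == other.step
            and self.slide == other.slide
            and list(self.chrom_sizes.items()) == list(other.chrom_sizes.items())
        )


def make_bins(chrom_sizes: ChromSizes, step: int, slide: int) -> BinGrid:
    """Build the sliding-bin grid (validates ``step`` and ``slide``)."""
    return BinGrid(chrom_sizes, int(step), int(slide))


@dataclass
class BinCounts:
    """Per-bin raw, CPM, and control-scaled counts on a :class:`BinGrid`.

    ``scaled`` equals ``raw`` (as float) until a control is applied.
    ``sample_total`` is the library depth used for CPM normalization.
    """

    grid: BinGrid
    raw: np.ndarray
    sample_total: int
    scaled: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=np.int64)
        if self.raw.shape != (self.grid.total_bins,):
            raise ValueError("raw counts incongruent with grid")
        if self.sample_total < 1:
            raise ValueError("sample_total must be >= 1")
        if self.scaled is None:
            self.scaled = self.raw.astype(float)
        else:
            self.scaled = np.asarray(self.scaled, dtype=float)
            if self.scaled.shape != self.raw.shape:
                raise ValueError("scaled counts incongruent with grid")

    @property
    def cpm(self) -> np.ndarray:
        """Counts per million: ``raw * 1e6 / sample_total``."""
        return self.raw * 1e6 / self.sample_total

    @property
    def test_counts(self) -> np.ndarray:
        """Integerized counts entering the binomial test: ``scaled`` rounded
        half-away-from-zero (counts are non-negative, so ``floor(x + 0.5)``)."""
        return np.floor(self.scaled + 0.5).astype(np.int64)


def count_fragments(grid: BinGrid, frags: FragmentSet) -> BinCounts:
    """Count fragments overlapping each bin by >= 1 bp.

    A fragment ``[s, e)`` overlaps bin ``[b, min(b + step, L))`` iff
    ``b < e`` and ``b + step > s`` (the chromosome end ``L`` exceeds ``s``
    for any valid fragment), i.e. the bin start lies in ``(s - step, e)``.
    With starts on the ``slide`` grid this is a contiguous index range, so
    counting is a difference-array accumulation, O(fragments + bins).
    """
    frags.validate_against(grid.chrom_sizes)
    raw = np.zeros(grid.total_bins, dtype=np.int64)
    offsets = grid.offsets
    for chrom in grid.chrom_sizes:
        arr = frags.intervals(chrom)
        if arr.shape[0] == 0:
            continue
        n = grid.n_bins(chrom)
        s = arr[:, 0]
        e = arr[:, 1]
        i_min = np.maximum((s - grid.step) // grid.slide + 1, 0)
        i_max = np.minimum((e - 1) // grid.slide, n - 1)
        diff = np.zeros(n + 1, dtype=np.int64)
        np.add.at(diff, i_min, 1)
        np.add.at(diff, i_max + 1, -1)
        off = offsets[chrom]
        raw[off : off + n] = np.cumsum(diff)[:n]
    total = frags.total
    if total < 1:
        raise ValueError("fragment set is empty; cannot compute CPM")
    return BinCounts(grid=grid, raw=raw, sample_total=total)


def scale_to_control(sample: BinCounts, control: BinCounts) -> BinCounts:
    """Scale sample bins against a negative control, per bin::

        CPM(sample) > CPM(control):  scaled = raw_sample * (1 - CPM(control)/CPM(sample))
        otherwise:                   scaled = 0

    The comparison is on the CPM scale so libraries of different depth are
    commensurable; equality (including both zero) yields 0. The result never
    exceeds the raw sample count.
    """
    if not sample.grid.same_grid(control.grid):
        raise ValueError("sample and control bin grids differ")
    cpm_s = sample.cpm
    cpm_c = control.cpm
    scaled = np.zeros_like(cpm_s)
    mask = cpm_s > cpm_c
    scaled[mask] = sample.raw[mask] * (1.0 - cpm_c[mask] / cpm_s[mask])
    return BinCounts(
        grid=sample.grid,
        raw=sample.raw,
        sample_total=sample.sample_total,
        scaled=scaled,
    )


def write_bedgraph(
    counts: BinCounts, path: str | os.PathLike, which: str = "scaled"
) -> None:
    """Export per-bin values as bedGraph (chrom, start, end, value).

    Overlapping bins are written as-is, one row per bin; intended for
    inspection rather than browser-exact coverage.
    """
    values = {"raw": counts.raw, "cpm": counts.cpm, "scaled": counts.scaled}[which]
    grid = counts.grid
    offsets = grid.offsets
    with open(path, "w") as fh:
        for chrom in grid.chrom_sizes:
            off = offsets[chrom]
            starts = grid.starts(chrom)
            ends = grid.ends(chrom)
            vals = values[off : off + starts.size]
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
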