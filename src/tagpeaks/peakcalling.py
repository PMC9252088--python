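"""Binomial significance testing of bins and merging into peaks.

The null model treats the library's ``n`` fragments as trials and asks, per
bin, whether its count ``x`` is surprisingly large under a genome-wide
success probability ``p``: the mean count of non-zero bins divided by ``n``.
Only bins with (integerized, control-scaled) count strictly greater than
``minreads`` are tested; their upper-tail binomial p-values are
Benjamini-Hochberg corrected over exactly that tested family, significant
bins (adjusted p <= threshold) are merged when separated by at most
``mdist`` bp, and merged peaks narrower than ``minwidth`` are discarded.

Narrow mode uses 100-bp bins on a 50-bp grid; broad mode (for domain-scale
marks such as H3K27me3) rewrites these to 5000/1000 before binning.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import binom

from .coverage import BinCounts, count_fragments, make_bins, scale_to_control
from .io_formats import ChromSizes, FragmentSet, write_bed

__all__ = [
    "BinomialModel",
    "CallParams",
    "Peak",
    "PeakSet",
    "estimate_model",
    "bin_pvalue",
    "bh_adjust",
    "test_bins",
    "merge_significant",
    "call_peaks",
]

# Cap on the BED score column, -log10(min adjusted p); matches the ceiling
# conventionally used in narrowPeak files.
SCORE_CAP = 3100.0

BROAD_STEP = 5000
BROAD_SLIDE = 1000


@dataclass(frozen=True)
class BinomialModel:
    """Genome-wide null for bin counts: ``X ~ Binomial(n, p)``.

    ``n`` is the library fragment total; ``n * p`` equals the mean count of
    non-zero bins.
    """

    n: int
    p: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie in (0, 1), got {self.p}")


@dataclass(frozen=True)
class CallParams:
    """Peak-calling parameters (defaults are the caller's published ones)."""

    step: int = 100
    slide: int = 50
    minreads: int = 15
    pthresh: float = 0.05
    mdist: int = 150
    minwidth: int = 150
    broad: bool = False

    def __post_init__(self):
        for name in ("step", "slide", "minreads", "mdist", "minwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.pthresh <= 1.0):
            raise ValueError("pthresh must lie in (0, 1]")

    def resolve(self) -> "CallParams":
        """Apply the broad flag: 5000-bp bins on a 1000-bp grid. Other
        parameters (notably ``mdist``) are left under user control."""
        if self.broad:
            return replace(self, step=BROAD_STEP, slide=BROAD_SLIDE)
        return self


@dataclass(frozen=True)
class Peak:
    """A merged run of significant bins, 0-based half-open."""

    chrom: str
    start: int
    end: int
    min_qvalue: float
    n_bins: int
    max_count: int

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def score(self) -> float:
        """-log10 of the best adjusted p over merged bins, capped."""
        if self.min_qvalue <= 0.0:
            return SCORE_CAP
        return min(-np.log10(self.min_qvalue), SCORE_CAP)


class PeakSet:
    """Ordered, per-chromosome disjoint collection of called peaks."""

    def __init__(
        self,
        peaks: list[Peak],
        params: CallParams | None = None,
        sample: str | None = None,
        info: dict | None = None,
        chrom_order: list[str] | None = None,
    ):
        self.peaks = list(peaks)
        self.params = params
        self.sample = sample
        self.info = dict(info or {})
        self.chrom_order = list(chrom_order) if chrom_order else None
        self._check_sorted_disjoint()

    def _check_sorted_disjoint(self) -> None:
        by_chrom: dict[str, Peak] = {}
        for pk in self.peaks:
            prev = by_chrom.get(pk.chrom)
            if prev is not None and pk.start < prev.end:
                raise ValueError(
                    f"peaks overlap or are unsorted on {pk.chrom}: "
                    f"{prev.start}-{prev.end} then {pk.start}-{pk.end}"
                )
            by_chrom[pk.chrom] = pk

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "min_qvalue": [p.min_qvalue for p in self.peaks],
                "n_bins": [p.n_bins for p in self.peaks],
                "max_count": [p.max_count for p in self.peaks],
            }
        )

    def write_bed(self, path: str | os.PathLike) -> None:
        """Serialize as BED6-like rows: chrom, start, end, name, score."""
        prefix = self.sample or "peak"
        rows = [
            (p.chrom, p.start, p.end, f"{prefix}_{i + 1}", f"{p.score:.4f}")
            for i, p in enumerate(self.peaks)
        ]
        write_bed(rows, path, chrom_order=self.chrom_order)


def estimate_model(counts, n: int | None = None) -> BinomialModel:
    """Estimate the binomial null from per-bin counts.

    ``p`` is the mean of the non-zero (integerized, control-scaled) bin
    counts divided by ``n``; ``n`` is the library fragment total. Accepts a
    :class:`~tagpeaks.coverage.BinCounts` (``n`` taken from its
    ``sample_total``) or a plain count array with ``n`` given.

    Raises
    ------
    ValueError
        If coverage is all zero ("no signal") or the estimate leaves (0, 1).
    """
    if isinstance(counts, BinCounts):
        arr = counts.test_counts
        n = counts.sample_total
    else:
        arr = np.asarray(counts)
        if n is None:
            raise ValueError("n (library fragment total) is required")
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise ValueError("no signal: all bins have zero coverage")
    p = float(nonzero.mean()) / n
    return BinomialModel(n=int(n), p=p)


def bin_pvalue(x, model: BinomialModel):
    """Upper-tail probability ``P(X >= x)`` for ``X ~ Binomial(n, p)``.

    Exact to double precision via the regularized incomplete beta (survival)
    function. ``x`` may be a scalar or array; ``x > n`` is an error.
    """
    x = np.asarray(x)
    if np.any(x < 0) or np.any(x > model.n):
        raise ValueError(f"x must lie in [0, n={model.n}]")
    result = binom.sf(x - 1, model.n, model.p)
    if result.ndim == 0:
        return float(result)
    return result


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, set ``q_i = p_i * m / i``, enforce monotonicity from the
    largest rank downward, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = ranked
    return out


def test_bins(counts: BinCounts, params: CallParams) -> pd.DataFrame:
    """Test bins against the genome-wide binomial null.

    Only bins whose integerized count is strictly greater than
    ``params.minreads`` enter the test; BH correction runs over exactly that
    family and a bin is significant iff its adjusted p <= ``params.pthresh``.

    Returns a DataFrame over tested bins with columns
    ``chrom, start, end, count, pvalue, qvalue, significant``.
    """
    model = estimate_model(counts)
    test_counts = counts.test_counts
    tested = np.flatnonzero(test_counts > params.minreads)
    frame = counts.grid.locate(tested)
    frame["count"] = test_counts[tested]
    if tested.size:
        pvals = bin_pvalue(frame["count"].to_numpy(), model)
        qvals = bh_adjust(np.atleast_1d(pvals))
    else:
        pvals = np.empty(0)
        qvals = np.empty(0)
    frame["pvalue"] = pvals
    frame["qvalue"] = qvals
    frame["significant"] = frame["qvalue"] <= params.pthresh
    frame.attrs["model"] = model
    return frame


def merge_significant(
    bins: pd.DataFrame,
    mdist: int,
    minwidth: int,
    params: CallParams | None = None,
    sample: str | None = None,
    chrom_order: list[str] | None = None,
    info: dict | None = None,
) -> PeakSet:
    """Merge significant bins into peaks.

    Two bin runs merge iff the gap between them (next start minus previous
    end) is at most ``mdist``; overlapping bins always merge. Bins on
    different chromosomes never merge. Merged peaks narrower than
    ``minwidth`` are discarded. Per-peak statistics: minimum adjusted p,
    number of merged bins, maximum bin count.

    ``bins`` needs columns ``chrom, start, end`` and optionally
    ``count, qvalue`` (defaulted when absent, e.g. for plain intervals).
    """
    bins = bins.copy()
    if "qvalue" not in bins:
        bins["qvalue"] = np.nan
    if "count" not in bins:
        bins["count"] = 0
    peaks: list[Peak] = []
    if chrom_order is not None:
        chrom_iter = [c for c in chrom_order if (bins["chrom"] == c).any()]
    else:
        chrom_iter = list(dict.fromkeys(bins["chrom"]))
    for chrom in chrom_iter:
        sub = bins[bins["chrom"] == chrom].sort_values(
            ["start", "end"], kind="stable"
        )
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        qvals = sub["qvalue"].to_numpy(dtype=float)
        cnts = sub["count"].to_numpy()
        if starts.size == 0:
            continue
        run_end = np.maximum.accumulate(ends)
        new_run = np.empty(starts.size, dtype=bool)
        new_run[0] = True
        new_run[1:] = starts[1:] - run_end[:-1] > mdist
        group = np.cumsum(new_run) - 1
        for g in range(group[-1] + 1):
            sel = group == g
            start = int(starts[sel].min())
            end = int(ends[sel].max())
            if end - start < minwidth:
                continue
            qv = qvals[sel]
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    min_qvalue=float(np.nanmin(qv)) if np.any(~np.isnan(qv)) else float("nan"),
                    n_bins=int(sel.sum()),
                    max_count=int(cnts[sel].max()),
                )
            )
    return PeakSet(peaks, params=params, sample=sample, info=info,
                   chrom_order=chrom_order)


def call_peaks(
    sample: FragmentSet,
    control: FragmentSet | None,
    chrom_sizes: ChromSizes,
    params: CallParams = CallParams(),
    sample_name: str | None = None,
) -> PeakSet:
    """Run the full pipeline: bin, count, scale, test, correct, merge.

    Fully deterministic: identical inputs and parameters yield identical
    peaks (and byte-identical BED output).
    """
    resolved = params.resolve()
    grid = make_bins(chrom_sizes, resolved.step, resolved.slide)
    counts = count_fragments(grid, sample)
    if control is not None:
        control_counts = count_fragments(grid, control)
        counts = scale_to_control(counts, control_counts)
    if not np.any(counts.test_counts > 0):
        # Nothing testable (e.g. a sample scaled against itself): no peaks.
        return PeakSet(
            [], params=resolved, sample=sample_name,
            info={"n": sample.total, "p": None, "bins_tested": 0,
                  "bins_significant": 0},
            chrom_order=chrom_sizes.names,
        )
    tested = test_bins(counts, resolved)
    model: BinomialModel = tested.attrs["model"]
    sig = tested[tested["significant"]]
    peakset = merge_significant(
        sig,
        mdist=resolved.mdist,
        minwidth=resolved.minwidth,
        params=resolved,
        sample=sample_name,
        chrom_order=chrom_sizes.names,
        info={
            "n": model.n,
            "p": model.p,
            "bins_tested": int(len(tested)),
            "bins_significant": int(sig.shape[0]),
        },
    )
    return peakset
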