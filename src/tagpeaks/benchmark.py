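"""Evaluation machinery: consensus peaks, standards, ROC/PR, peak statistics.

High-confidence (consensus) peaks are the merged union of replicate peak
sets, keeping blocks supported by at least two biological replicates. An
external "standard" peak set (e.g. ChIP-seq peaks with -log10 p scores) is
filtered and gap-merged before use as truth. Consensus peaks are ranked by
their fragment counts and swept over unique ranking values to fill out a
confusion matrix per threshold; ROC (TPR vs FPR) and precision-recall
curves are summarized by trapezoid-rule areas.

The confusion-matrix universe is the set of ranked consensus intervals:
a true negative is an interval below the score threshold that does not
overlap the standard. Overlap means >= 1 bp throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import FragmentSet, ScoredInterval
from .peakcalling import PeakSet

__all__ = [
    "ConsensusPeaks",
    "EvalCurve",
    "high_confidence",
    "prepare_standard",
    "rank_counts",
    "roc_pr",
    "peak_stats",
]


def _as_interval_rows(peaks) -> list[tuple[str, int, int]]:
    """Normalize a PeakSet / DataFrame / iterable into (chrom, start, end)."""
    if isinstance(peaks, PeakSet):
        return [(p.chrom, p.start, p.end) for p in peaks]
    if isinstance(peaks, pd.DataFrame):
        return list(
            zip(peaks["chrom"], peaks["start"].astype(int), peaks["end"].astype(int))
        )
    return [(r[0], int(r[1]), int(r[2])) for r in peaks]


@dataclass
class ConsensusPeaks:
    """Disjoint consensus intervals with per-interval replicate support."""

    frame: pd.DataFrame  # columns: chrom, start, end, support

    def __len__(self) -> int:
        return int(self.frame.shape[0])

    def intervals(self) -> list[tuple[str, int, int]]:
        return list(
            zip(self.frame["chrom"], self.frame["start"], self.frame["end"])
        )


def _merge_blocks(
    rows: list[tuple[str, int, int, int]], gap: int
) -> list[tuple[str, int, int, set[int]]]:
    """Merge labelled intervals into blocks; two intervals chain when the gap
    between them is <= ``gap`` (gap < 0 means they must overlap by >= 1 bp).
    Returns per-block (chrom, start, end, contributing labels)."""
    blocks: list[tuple[str, int, int, set[int]]] = []
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, start, end, label in rows:
        by_chrom.setdefault(chrom, []).append((start, end, label))
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom])
        cur_start, cur_end, labels = items[0][0], items[0][1], {items[0][2]}
        for start, end, label in items[1:]:
            if start - cur_end <= gap:
                cur_end = max(cur_end, end)
                labels.add(label)
            else:
                blocks.append((chrom, cur_start, cur_end, labels))
                cur_start, cur_end, labels = start, end, {label}
        blocks.append((chrom, cur_start, cur_end, labels))
    return blocks


def high_confidence(replicate_peaks, min_support: int = 2) -> ConsensusPeaks:
    """Consensus peaks across biological replicates.

    The union of all replicate peaks is merged into disjoint blocks (chains
    of >= 1 bp overlaps); a block's support is the number of distinct
    replicates contributing at least one overlapping peak, and blocks with
    support below ``min_support`` are dropped.
    """
    replicate_peaks = list(replicate_peaks)
    if len(replicate_peaks) < min_support:
        raise ValueError(
            f"need at least min_support={min_support} replicates, "
            f"got {len(replicate_peaks)}"
        )
    rows: list[tuple[str, int, int, int]] = []
    for rep_idx, peaks in enumerate(replicate_peaks):
        for chrom, start, end in _as_interval_rows(peaks):
            rows.append((chrom, start, end, rep_idx))
    if not rows:
        return ConsensusPeaks(
            pd.DataFrame(columns=["chrom", "start", "end", "support"])
        )
    # gap=-1: strict >=1 bp overlap chaining (half-open adjacency is not overlap)
    blocks = _merge_blocks(rows, gap=-1)
    kept = [
        (chrom, start, end, len(labels))
        for chrom, start, end, labels in blocks
        if len(labels) >= min_support
    ]
    return ConsensusPeaks(
        pd.DataFrame(kept, columns=["chrom", "start", "end", "support"])
    )


def prepare_standard(
    scored: list[ScoredInterval],
    min_neglog10p: float = 10.0,
    merge_within: int = 1000,
) -> pd.DataFrame:
    """Filter and gap-merge a scored standard peak set.

    Intervals with score (a -log10 p-value) strictly greater than
    ``min_neglog10p`` survive; survivors separated by at most
    ``merge_within`` bp are merged. Idempotent.
    """
    survivors = [
        (iv.chrom, int(iv.start), int(iv.end), 0)
        for iv in scored
        if iv.score > min_neglog10p
    ]
    if not survivors:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    blocks = _merge_blocks(survivors, gap=merge_within)
    return pd.DataFrame(
        [(c, s, e) for c, s, e, _ in blocks], columns=["chrom", "start", "end"]
    )


def rank_counts(consensus: ConsensusPeaks, frags: FragmentSet) -> list[ScoredInterval]:
    """Score each consensus interval by its overlapping-fragment count."""
    out: list[ScoredInterval] = []
    frame = consensus.frame
    for chrom, sub in frame.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        counts = frags.count_overlaps(chrom, starts, ends)
        for s, e, c in zip(starts, ends, counts):
            out.append(ScoredInterval(chrom, int(s), int(e), float(c)))
    # preserve the frame's row order
    order = {
        (c, int(s), int(e)): i
        for i, (c, s, e) in enumerate(
            zip(frame["chrom"], frame["start"], frame["end"])
        )
    }
    out.sort(key=lambda iv: order[(iv.chrom, iv.start, iv.end)])
    return out


@dataclass
class EvalCurve:
    """Threshold-swept confusion-matrix summary with a trapezoidal area.

    ``kind`` is "roc" (TPR vs FPR) or "pr" (precision vs recall).
    ``degenerate`` flags curves whose rates are undefined (e.g. an empty
    standard leaves recall undefined); then ``area`` is NaN.
    """

    kind: str
    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    x: np.ndarray  # FPR (roc) or recall (pr)
    y: np.ndarray  # TPR (roc) or precision (pr)
    area: float = field(init=False)
    degenerate: bool = False

    def __post_init__(self):
        if self.degenerate or self.x.size < 2:
            self.area = float("nan")
            return
        order = np.argsort(self.x, kind="stable")
        self.area = float(np.trapezoid(self.y[order], self.x[order]))

    def to_frame(self) -> pd.DataFrame:
        cols = {"threshold": self.thresholds, "tp": self.tp, "fp": self.fp,
                "tn": self.tn, "fn": self.fn}
        if self.kind == "roc":
            cols["fpr"] = self.x
            cols["tpr"] = self.y
        else:
            cols["recall"] = self.x
            cols["precision"] = self.y
        return pd.DataFrame(cols)


def _overlaps_standard(
    ranked: list[ScoredInterval], standard: pd.DataFrame | list
) -> np.ndarray:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in _as_interval_rows(standard):
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    labels = np.zeros(len(ranked), dtype=bool)
    for i, iv in enumerate(ranked):
        tree = trees.get(iv.chrom)
        labels[i] = tree is not None and tree.overlaps(iv.start, iv.end)
    return labels


def roc_pr(
    ranked: list[ScoredInterval], standard
) -> tuple[EvalCurve, EvalCurve]:
    """ROC and PR curves of count-ranked intervals against a standard.

    For each unique ranking value ``t`` (descending, plus a sentinel above
    the maximum for the all-negative anchor and 0 for the all-positive
    anchor), predicted positives are intervals with score >= t; actual
    positives are intervals overlapping the standard by >= 1 bp. Areas are
    trapezoidal over the swept points, so the ROC sweep spans (0,0) to (1,1).

    An empty standard (or a universe with no negatives) yields a curve
    flagged degenerate rather than a division by zero.
    """
    if not ranked:
        raise ValueError("ranked interval list is empty")
    scores = np.array([iv.score for iv in ranked], dtype=float)
    labels = _overlaps_standard(ranked, standard)
    pos = int(labels.sum())
    neg = int(labels.size - pos)

    thresholds = np.unique(scores)[::-1]
    sentinel = float(thresholds[0]) + 1.0
    sweep = [sentinel, *thresholds.tolist()]
    if sweep[-1] > 0.0:
        sweep.append(0.0)
    sweep_arr = np.array(sweep, dtype=float)

    tp = np.empty(sweep_arr.size, dtype=np.int64)
    fp = np.empty(sweep_arr.size, dtype=np.int64)
    for i, t in enumerate(sweep_arr):
        predicted = scores >= t
        tp[i] = int((predicted & labels).sum())
        fp[i] = int((predicted & ~labels).sum())
    fn = pos - tp
    tn = neg - fp

    degenerate = pos == 0 or neg == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(pos > 0, tp / max(pos, 1), np.nan)
        fpr = np.where(neg > 0, fp / max(neg, 1), np.nan)
    roc = EvalCurve(
        kind="roc", thresholds=sweep_arr, tp=tp, fp=fp, tn=tn, fn=fn,
        x=fpr, y=tpr, degenerate=degenerate,
    )

    predicted_any = (tp + fp) > 0
    pr_degenerate = pos == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted_any, tp / np.maximum(tp + fp, 1), np.nan)
        recall = np.where(pos > 0, tp / max(pos, 1), np.nan)
    keep = predicted_any
    pr = EvalCurve(
        kind="pr",
        thresholds=sweep_arr[keep],
        tp=tp[keep], fp=fp[keep], tn=tn[keep], fn=fn[keep],
        x=recall[keep] if not pr_degenerate else np.full(int(keep.sum()), np.nan),
        y=precision[keep],
        degenerate=pr_degenerate,
    )
    return roc, pr


def peak_stats(peaks, frags: FragmentSet | None = None) -> pd.DataFrame:
    """Per-peak width, fragment count, and distance to the nearest peak.

    Nearest distance is the minimum gap to another peak on the same
    chromosome (0 if touching or overlapping), NaN for per-chromosome
    singletons. ``frags`` may be omitted, in which case counts are NaN.
    """
    rows = _as_interval_rows(peaks)
    if not rows:
        raise ValueError("peak_stats needs at least one peak")
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    frame["width"] = frame["end"] - frame["start"]
    if frags is not None:
        counts = np.empty(frame.shape[0], dtype=np.int64)
        for chrom, sub in frame.groupby("chrom", sort=False):
            counts[sub.index] = frags.count_overlaps(
                chrom,
                sub["start"].to_numpy(dtype=np.int64),
                sub["end"].to_numpy(dtype=np.int64),
            )
        frame["count"] = counts
    else:
        frame["count"] = np.nan
    dist = np.full(frame.shape[0], np.nan)
    for chrom, sub in frame.groupby("chrom", sort=False):
        if sub.shape[0] < 2:
            continue
        sub = sub.sort_values(["start", "end"], kind="stable")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = sub.index.to_numpy()
        for i in range(len(idx)):
            gaps = []
            if i > 0:
                gaps.append(starts[i] - ends[:i].max())
            if i < len(idx) - 1:
                gaps.append(starts[i + 1 :].min() - ends[i])
            dist[idx[i]] = max(min(gaps), 0)
    frame["nearest_dist"] = dist
    return frame
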