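"""Genome-wide scanning and Grad-CAM annotation condensation.

The trained classifier scores 4 kb sliding windows (500 bp stride); windows
with probability strictly greater than 0.5 are positive.  Merging the
positive windows gives the *original* annotation.  Position-wise Grad-CAM
maps of all positive windows are pooled to a single global cutoff — the
mean score over every bin of every positive window — and bins strictly
above the cutoff, unioned across overlapping windows, are merged into the
*refined* annotation: core enhancers at 10 bp resolution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .gradcam import positionwise_scores
from .model import EnhancerClassifier
from .signal_io import (AssayPanel, BIN_SIZE, GenomicInterval, STEP_SIZE,
                        WINDOW_SIZE, extract_matrix_batch, sliding_windows,
                        write_bed)

__all__ = ["ScanResult", "RefinedAnnotation", "scan", "merge_original",
           "global_cutoff", "refine_window", "condense",
           "DEFAULT_THRESHOLD"]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5


@dataclass
class ScanResult:
    """Sliding-window probabilities over a genome."""

    windows: list                     # GenomicIntervals, sorted by coordinate
    probabilities: np.ndarray         # (n,), in (0, 1)
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if len(self.windows) != len(self.probabilities):
            raise ValueError("windows/probabilities length mismatch")

    @property
    def positive_mask(self) -> np.ndarray:
        # strictly greater: a window scoring exactly at threshold is negative
        return self.probabilities > self.threshold

    @property
    def positive_windows(self) -> list:
        m = self.positive_mask
        return [w for w, keep in zip(self.windows, m) if keep]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tprobability\tpositive\n")
            for w, p, pos in zip(self.windows, self.probabilities,
                                 self.positive_mask):
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{p:.6f}"
                         f"\t{int(pos)}\n")


@dataclass
class RefinedAnnotation:
    """Condensed enhancer intervals at 10 bp granularity."""

    intervals: list                   # sorted, non-overlapping
    scores: list = field(default_factory=list)   # per-interval mean Grad-CAM
    cutoff: float = float("nan")

    def total_coverage(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def to_bed(self, path) -> None:
        write_bed(path, self.intervals,
                  scores=self.scores if self.scores else None)


def scan(model: EnhancerClassifier, tracks, chrom_sizes: Mapping[str, int],
         threshold: float = DEFAULT_THRESHOLD, window: int = WINDOW_SIZE,
         step: int = STEP_SIZE, bin_size: int = BIN_SIZE,
         panel: Optional[AssayPanel] = None,
         batch_size: int = 256) -> ScanResult:
    """Score sliding windows across every chromosome in `chrom_sizes`."""
    panel = panel or AssayPanel()
    windows = []
    for chrom in chrom_sizes:
        if chrom_sizes[chrom] >= window:
            windows.extend(sliding_windows(chrom_sizes[chrom], window, step,
                                           chrom=chrom))
    probs = np.empty(len(windows), dtype=np.float64)
    for lo in range(0, len(windows), batch_size):
        chunk = windows[lo:lo + batch_size]
        X = extract_matrix_batch(tracks, chunk, panel, bin_size)
        probs[lo:lo + len(chunk)] = model.predict_proba(X)[:, 1]
    logger.info("scanned %d windows, %d positive at threshold %.2f",
                len(windows), int((probs > threshold).sum()), threshold)
    return ScanResult(windows=windows, probabilities=probs,
                      threshold=threshold)


def merge_original(intervals: Sequence[GenomicInterval]) -> list:
    """Union of overlapping or book-ended intervals (gap 0 merges)."""
    by_chrom: dict = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for chrom in sorted(by_chrom):
        merged: list = []
        for s, e in sorted(by_chrom[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out.extend(GenomicInterval(chrom, s, e) for s, e in merged)
    return out


def global_cutoff(maps) -> float:
    """Mean Grad-CAM score over every bin of every positive window.

    The mean is over all genomic positions pooled together (each window
    contributes its 400 bins, unweighted), so the cutoff is global and the
    filtering can only happen after all positive windows are processed.
    """
    maps = np.asarray(maps, dtype=np.float64)
    if maps.size == 0:
        raise ValueError("no position-wise maps; need >= 1 positive window")
    return float(maps.mean())


def refine_window(window: GenomicInterval, scores: np.ndarray, cutoff: float,
                  bin_size: int = BIN_SIZE) -> list:
    """Bins with score strictly above the cutoff, merged if adjacent,
    mapped back to genomic coordinates."""
    scores = np.asarray(scores)
    if len(window) != len(scores) * bin_size:
        raise ValueError(
            f"{len(scores)} scores at {bin_size} bp do not tile a "
            f"{len(window)} bp window")
    keep = scores > cutoff
    out = []
    start_bin = None
    for b, k in enumerate(keep):
        if k and start_bin is None:
            start_bin = b
        elif not k and start_bin is not None:
            out.append(GenomicInterval(
                window.chrom, window.start + start_bin * bin_size,
                window.start + b * bin_size))
            start_bin = None
    if start_bin is not None:
        out.append(GenomicInterval(
            window.chrom, window.start + start_bin * bin_size,
            window.start + len(keep) * bin_size))
    return out


def condense(scan_result: ScanResult, model: EnhancerClassifier, tracks,
             panel: Optional[AssayPanel] = None, bin_size: int = BIN_SIZE,
             batch_size: int = 128
             ) -> tuple[list, RefinedAnnotation]:
    """Original (merged positive windows) and refined (Grad-CAM) annotations.

    Position-wise maps are computed for every positive window, pooled into
    the global mean cutoff, thresholded per window, and unioned across
    overlapping windows on the genomic 10 bp grid: a bin is selected if any
    covering window selects it.  Refined intervals carry the mean Grad-CAM
    score of their bins (averaged across covering windows).
    """
    panel = panel or AssayPanel()
    positives = scan_result.positive_windows
    if not positives:
        warnings.warn("no positive windows; annotations are empty")
        return [], RefinedAnnotation(intervals=[], scores=[])
    original = merge_original(positives)

    n_bins = WINDOW_SIZE // bin_size
    maps = np.empty((len(positives), n_bins), dtype=np.float64)
    for lo in range(0, len(positives), batch_size):
        chunk = positives[lo:lo + batch_size]
        X = extract_matrix_batch(tracks, chunk, panel, bin_size)
        maps[lo:lo + len(chunk)] = positionwise_scores(model, X)
    cutoff = global_cutoff(maps)

    # genome-level 10 bp grid union; window starts are multiples of the
    # scan step, which the pipeline keeps a multiple of bin_size
    grids: dict = {}
    for win, smap in zip(positives, maps):
        if win.start % bin_size:
            raise ValueError("window starts must align to the bin grid")
        gsel, gsum, gcnt, glen = grids.setdefault(
            win.chrom, [set(), {}, {}, 0])
        base = win.start // bin_size
        keep = smap > cutoff
        for b in np.flatnonzero(keep):
            gsel.add(base + int(b))
        for b in range(n_bins):
            gb = base + b
            gsum[gb] = gsum.get(gb, 0.0) + float(smap[b])
            gcnt[gb] = gcnt.get(gb, 0) + 1

    intervals, scores = [], []
    for chrom in sorted(grids):
        gsel, gsum, gcnt, _ = grids[chrom]
        bins = sorted(gsel)
        run_start = None
        prev = None
        for gb in bins + [None]:
            if run_start is not None and (gb is None or gb != prev + 1):
                lo_b, hi_b = run_start, prev + 1
                intervals.append(GenomicInterval(
                    chrom, lo_b * bin_size, hi_b * bin_size))
                scores.append(float(np.mean(
                    [gsum[b] / gcnt[b] for b in range(lo_b, hi_b)])))
                run_start = None
            if gb is not None and run_start is None:
                run_start = gb
            prev = gb
    refined = RefinedAnnotation(intervals=intervals, scores=scores,
                                cutoff=cutoff)
    logger.info("original: %d elements (%d bp); refined: %d elements (%d bp)",
                len(original), sum(len(iv) for iv in original),
                len(intervals), refined.total_coverage())
    return original, refined
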