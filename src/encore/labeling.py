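"""Training-label construction from STARR-seq and chromatin peak sets.

Positives are STARR-seq peaks supported by open chromatin *and* at least one
active histone enhancer mark (>= 1 bp overlap).  Negatives are 4 kb windows
down-sampled from the background — the genome minus all positive windows and
minus every input peak set — at a configurable ratio (default 1:10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .signal_io import (AssayPanel, GenomicInterval, WINDOW_SIZE,
                        extract_matrix_batch, write_bed)

__all__ = ["LabeledWindow", "LabeledDataset", "call_positive_regions",
           "center_and_extend", "sample_negatives", "build_dataset",
           "DEFAULT_NEGATIVE_RATIO"]

DEFAULT_NEGATIVE_RATIO = 10


def _trees(intervals: Iterable[GenomicInterval]) -> dict:
    trees: dict = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _hits(trees: dict, iv: GenomicInterval) -> bool:
    t = trees.get(iv.chrom)
    return bool(t is not None and t.overlap(iv.start, iv.end))


def call_positive_regions(starr: Sequence[GenomicInterval],
                          accessibility: Sequence[GenomicInterval],
                          histone_sets: Sequence[Sequence[GenomicInterval]]
                          ) -> list:
    """STARR-seq peaks overlapping an accessibility peak AND >= 1 histone peak.

    Overlap means at least one shared base.  Each STARR peak is returned at
    most once, in input order.
    """
    acc = _trees(accessibility)
    hist = [_trees(hs) for hs in histone_sets]
    out, seen = [], set()
    for iv in starr:
        key = (iv.chrom, iv.start, iv.end)
        if key in seen:
            continue
        if _hits(acc, iv) and any(_hits(h, iv) for h in hist):
            out.append(iv)
            seen.add(key)
    return out


def center_and_extend(interval: GenomicInterval, length: int = WINDOW_SIZE,
                      chrom_length: int = None) -> GenomicInterval:
    """Fixed-length window centred on the interval midpoint.

    Windows that would cross a chromosome boundary are shifted minimally
    inward (never dropped), so positive counts are preserved.
    """
    if chrom_length is None:
        raise ValueError("chrom_length is required")
    if chrom_length < length:
        raise ValueError(
            f"chromosome ({chrom_length} bp) shorter than window ({length} bp)")
    start = interval.midpoint - length // 2
    start = min(max(start, 0), chrom_length - length)
    return GenomicInterval(interval.chrom, start, start + length)


def _background_start_ranges(chrom_sizes: Mapping[str, int],
                             masked: Sequence[GenomicInterval],
                             window: int) -> list:
    """Per-chromosome ranges of valid window starts avoiding all masks.

    Returns [(chrom, lo, hi)] where any start in [lo, hi) yields a window
    inside the chromosome that overlaps no masked interval.
    """
    by_chrom: dict = {c: [] for c in chrom_sizes}
    for iv in masked:
        if iv.chrom in by_chrom:
            by_chrom[iv.chrom].append((iv.start, iv.end))
    ranges = []
    for chrom, L in chrom_sizes.items():
        if L < window:
            continue
        merged = []
        for s, e in sorted(by_chrom[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        cursor = 0
        for s, e in merged + [(L, L)]:
            hi = min(s - window, L - window) + 1
            if hi > cursor:
                ranges.append((chrom, cursor, hi))
            cursor = max(cursor, e)
    return ranges


def sample_negatives(chrom_sizes: Mapping[str, int],
                     positives: Sequence[GenomicInterval],
                     ratio: int = DEFAULT_NEGATIVE_RATIO,
                     seed: int = 0,
                     masks: Sequence[GenomicInterval] = (),
                     window: int = WINDOW_SIZE) -> list:
    """Draw ratio * len(positives) background windows, seeded.

    Background excludes every positive region and every interval in `masks`
    (typically the raw STARR-seq and accessibility peak sets).  Distinct
    negative windows may overlap each other; none overlaps a mask.
    """
    if ratio < 1:
        raise ValueError("negative:positive ratio must be >= 1")
    if not positives:
        raise ValueError("need at least one positive region")
    n_needed = ratio * len(positives)
    ranges = _background_start_ranges(
        chrom_sizes, list(positives) + list(masks), window)
    counts = np.array([hi - lo for _, lo, hi in ranges], dtype=np.int64)
    total = int(counts.sum())
    if total < n_needed:
        raise ValueError(
            f"insufficient background space after masking: {total} candidate "
            f"starts for {n_needed} negatives")
    rng = np.random.default_rng(seed)
    picks = rng.choice(total, size=n_needed, replace=False)
    picks.sort()
    cum = np.concatenate(([0], np.cumsum(counts)))
    out = []
    for p in picks:
        i = int(np.searchsorted(cum, p, side="right") - 1)
        chrom, lo, _ = ranges[i]
        start = lo + int(p - cum[i])
        out.append(GenomicInterval(chrom, start, start + window))
    return out


@dataclass
class LabeledWindow:
    """One training window: matrix row + label + grouping tags."""

    matrix: np.ndarray          # (5, n_bins)
    label: int                  # 1 = active enhancer, 0 = background
    cell_type: str
    chrom: str

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class LabeledDataset:
    """Window matrices with binary labels and CV group tags.

    X: (n, 5, n_bins) float32; y: (n,) int8; chrom/cell_type: (n,) group
    tags for leave-one-chromosome-out / leave-one-cell-type-out schemes.
    """

    X: np.ndarray
    y: np.ndarray
    chrom: np.ndarray
    cell_type: np.ndarray
    windows: list = field(default_factory=list)
    panel: AssayPanel = field(default_factory=AssayPanel)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int8)
        self.chrom = np.asarray(self.chrom)
        self.cell_type = np.asarray(self.cell_type)
        n = len(self.X)
        if not (len(self.y) == len(self.chrom) == len(self.cell_type) == n):
            raise ValueError("inconsistent dataset field lengths")
        if self.windows and len(self.windows) != n:
            raise ValueError("windows length mismatch")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def __len__(self):
        return len(self.X)

    def __getitem__(self, i) -> LabeledWindow:
        return LabeledWindow(matrix=self.X[i], label=int(self.y[i]),
                             cell_type=str(self.cell_type[i]),
                             chrom=str(self.chrom[i]))

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            X=self.X[idx], y=self.y[idx], chrom=self.chrom[idx],
            cell_type=self.cell_type[idx],
            windows=[self.windows[i] for i in idx] if self.windows else [],
            panel=self.panel, metadata=dict(self.metadata))

    def save_npz(self, path) -> None:
        import json
        meta = {"panel": list(self.panel.assays),
                "accessibility": self.panel.accessibility,
                "metadata": self.metadata,
                "windows": [[w.chrom, w.start, w.end] for w in self.windows]}
        np.savez_compressed(
            path, X=self.X, y=self.y, chrom=self.chrom.astype(str),
            cell_type=self.cell_type.astype(str),
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load_npz(cls, path) -> "LabeledDataset":
        import json
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(bytes(npz["meta"]).decode())
            windows = [GenomicInterval(c, int(s), int(e))
                       for c, s, e in meta.get("windows", [])]
            return cls(X=npz["X"], y=npz["y"], chrom=npz["chrom"],
                       cell_type=npz["cell_type"], windows=windows,
                       panel=AssayPanel(tuple(meta["panel"]),
                                        meta["accessibility"]),
                       metadata=meta.get("metadata", {}))

    def to_bed(self, path) -> None:
        """Windows as BED with the label in the score column."""
        write_bed(path, self.windows, scores=self.y.astype(float))


def build_dataset(tracks, positives: Sequence[GenomicInterval],
                  negatives: Sequence[GenomicInterval],
                  panel: Optional[AssayPanel] = None,
                  cell_type: str = "NA",
                  metadata: Optional[dict] = None) -> LabeledDataset:
    """Assemble a LabeledDataset from 4 kb positive/negative windows."""
    panel = panel or AssayPanel()
    if not negatives:
        warnings.warn("no negative windows supplied; dataset is single-class")
    windows = list(positives) + list(negatives)
    for w in windows:
        if len(w) != WINDOW_SIZE:
            raise ValueError(
                f"all windows must be {WINDOW_SIZE} bp; got {len(w)} at "
                f"{w.chrom}:{w.start}-{w.end}")
    X = extract_matrix_batch(tracks, windows, panel)
    y = np.concatenate([np.ones(len(positives), dtype=np.int8),
                        np.zeros(len(negatives), dtype=np.int8)])
    chrom = np.array([w.chrom for w in windows])
    ct = np.full(len(windows), cell_type)
    return LabeledDataset(X=X, y=y, chrom=chrom, cell_type=ct,
                          windows=windows, panel=panel,
                          metadata=metadata or {})
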