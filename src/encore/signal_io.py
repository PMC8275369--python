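"""Interval and signal-track I/O, 10 bp binning, and window extraction.

Coordinates follow the BED convention throughout: 0-based, half-open
[start, end).  Signal tracks are dense per-chromosome coverage arrays;
absent coverage is 0, never NaN, so every extracted matrix is finite.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

WINDOW_SIZE = 4000      # default classifier window, bp
BIN_SIZE = 10           # signal aggregation resolution, bp
STEP_SIZE = 500         # genome-scan stride, bp
N_ASSAYS = 5
N_BINS = WINDOW_SIZE // BIN_SIZE
ACCESSIBILITY_ROW = 2   # accessibility sits in the middle of the matrix

# Default row order; only the accessibility-in-the-middle constraint is
# structural, the histone ordering is configurable.
DEFAULT_ASSAYS = ("H3K4me3", "H3K9ac", "accessibility", "H3K27ac", "H3K4me1")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})")

    def __len__(self):
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # floor midpoint of [start, end)
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True)
class AssayPanel:
    """Ordered panel of the five epigenetic assays.

    The chromatin-accessibility track must occupy the middle row (index 2)
    so the cross-assay convolution filters see it flanked by histone marks.
    """

    assays: tuple = DEFAULT_ASSAYS
    accessibility: str = "accessibility"

    def __post_init__(self):
        if len(self.assays) != N_ASSAYS:
            raise ValueError(f"panel must list exactly {N_ASSAYS} assays")
        if len(set(self.assays)) != N_ASSAYS:
            raise ValueError("panel assays must be unique")
        if self.accessibility not in self.assays:
            raise ValueError("accessibility assay missing from panel")
        if self.assays.index(self.accessibility) != ACCESSIBILITY_ROW:
            raise ValueError(
                f"accessibility must be row {ACCESSIBILITY_ROW} of the panel")

    @property
    def accessibility_row(self) -> int:
        return ACCESSIBILITY_ROW

    def index(self, assay: str) -> int:
        return self.assays.index(assay)


@dataclass
class SignalTrack:
    """Per-chromosome base-resolution coverage for one assay.

    `values` maps chromosome name to a non-negative float array; positions
    beyond the stored array (or chromosomes absent from the mapping) read
    as 0 coverage.
    """

    assay: str
    values: dict = field(default_factory=dict)

    def chrom_length(self, chrom: str) -> int:
        arr = self.values.get(chrom)
        return 0 if arr is None else len(arr)

    def window_values(self, window: GenomicInterval) -> np.ndarray:
        """Base values over the window, zero-filled outside coverage."""
        arr = self.values.get(window.chrom)
        n = len(window)
        out = np.zeros(n, dtype=np.float32)
        if arr is None:
            return out
        lo = min(window.start, len(arr))
        hi = min(window.end, len(arr))
        if hi > lo:
            out[lo - window.start:hi - window.start] = arr[lo:hi]
        return out

    @classmethod
    def from_bedgraph(cls, path, assay: str,
                      chrom_sizes: Optional[Mapping[str, int]] = None
                      ) -> "SignalTrack":
        """Load a bedGraph (chrom, start, end, value) into dense arrays."""
        intervals = read_intervals(path, min_columns=4, value_column=3)
        sizes: dict = dict(chrom_sizes) if chrom_sizes else {}
        if not sizes:
            for iv in intervals:
                sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), iv.end)
        values = {c: np.zeros(n, dtype=np.float32) for c, n in sizes.items()}
        for iv in intervals:
            arr = values.get(iv.chrom)
            if arr is None:
                continue
            v = iv.score if iv.score is not None else 0.0
            if v < 0 or not np.isfinite(v):
                raise ValueError(
                    f"negative or non-finite signal {v} at "
                    f"{iv.chrom}:{iv.start}-{iv.end}")
            arr[iv.start:min(iv.end, len(arr))] = v
        return cls(assay=assay, values=values)

    @classmethod
    def from_bigwig(cls, path, assay: str,
                    chroms: Optional[Iterable[str]] = None) -> "SignalTrack":
        """Load base-resolution values from a bigWig file (via pyBigWig)."""
        import pyBigWig

        bw = pyBigWig.open(str(path))
        try:
            names = list(chroms) if chroms else list(bw.chroms())
            values = {}
            for chrom in names:
                n = bw.chroms(chrom)
                if not n:
                    continue
                arr = np.nan_to_num(
                    np.asarray(bw.values(chrom, 0, n), dtype=np.float32))
                np.maximum(arr, 0.0, out=arr)
                values[chrom] = arr
        finally:
            bw.close()
        return cls(assay=assay, values=values)

    def to_bedgraph(self, path) -> None:
        """Write the track as run-length-encoded bedGraph."""
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                arr = self.values[chrom]
                if len(arr) == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0.0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def load_track(path, assay: str,
               chrom_sizes: Optional[Mapping[str, int]] = None) -> SignalTrack:
    """Dispatch on extension: .bw/.bigwig via pyBigWig, else bedGraph."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".bw", ".bigwig"):
        return SignalTrack.from_bigwig(path, assay)
    return SignalTrack.from_bedgraph(path, assay, chrom_sizes)


@dataclass
class WindowMatrix:
    """One 4 kb window as a 5 x 400 matrix of 10 bp bin-mean signal."""

    window: GenomicInterval
    data: np.ndarray
    panel: AssayPanel = field(default_factory=AssayPanel)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.shape != (N_ASSAYS, len(self.window) // BIN_SIZE):
            raise ValueError(
                f"matrix shape {self.data.shape} inconsistent with a "
                f"{len(self.window)} bp window at {BIN_SIZE} bp bins")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("window matrix entries must be finite and >= 0")


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph lines, reporting the line number."""


def read_intervals(path, min_columns: int = 3,
                   value_column: Optional[int] = None) -> list:
    """Parse a BED-style file into GenomicIntervals, preserving order.

    Malformed lines raise :class:`BedParseError` naming the offending line.
    `value_column` (0-based), when given, is parsed into the interval score
    (bedGraph uses column 3).  Lines starting with ``track``, ``browser`` or
    ``#`` are skipped.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_columns:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >= {min_columns} "
                    f"tab-separated columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}") from exc
            score = None
            if value_column is not None:
                try:
                    score = float(fields[value_column])
                except (IndexError, ValueError) as exc:
                    raise BedParseError(
                        f"{path}: line {lineno}: missing or non-numeric "
                        f"value in column {value_column}") from exc
            elif len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            try:
                intervals.append(GenomicInterval(chrom, start, end, score))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(path, intervals: Iterable[GenomicInterval],
              scores: Optional[Sequence[float]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if scores is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{scores[i]:.6g}\n")
            elif iv.score is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{iv.score:.6g}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path) -> dict:
    """Two-column <chrom> <length> table."""
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(path, sizes: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, n in sizes.items():
            fh.write(f"{chrom}\t{n}\n")


def bin_signal(track: SignalTrack, window: GenomicInterval,
               bin_size: int = BIN_SIZE) -> np.ndarray:
    """Mean signal per `bin_size` bp bin across the window.

    Bin b covers bases [start + b*bin_size, start + (b+1)*bin_size);
    uncovered bases contribute 0 to the mean.
    """
    if len(window) % bin_size:
        raise ValueError(
            f"window length {len(window)} not divisible by bin size {bin_size}")
    vals = track.window_values(window)
    return vals.reshape(-1, bin_size).mean(axis=1)


def extract_window_matrix(tracks, window: GenomicInterval,
                          panel: Optional[AssayPanel] = None,
                          bin_size: int = BIN_SIZE) -> WindowMatrix:
    """Stack the five binned assay rows in panel order for one 4 kb window.

    `tracks` may be a mapping assay -> SignalTrack or a sequence of
    SignalTracks (matched to the panel by their `assay` labels, so argument
    order never changes row placement).
    """
    panel = panel or AssayPanel()
    if len(window) != WINDOW_SIZE:
        raise ValueError(f"window must be {WINDOW_SIZE} bp, got {len(window)}")
    by_assay = _tracks_by_assay(tracks)
    rows = []
    for assay in panel.assays:
        if assay not in by_assay:
            raise KeyError(f"missing track for assay {assay!r}")
        rows.append(bin_signal(by_assay[assay], window, bin_size))
    return WindowMatrix(window=window, data=np.stack(rows), panel=panel)


def _tracks_by_assay(tracks) -> dict:
    if isinstance(tracks, Mapping):
        return dict(tracks)
    return {t.assay: t for t in tracks}


def extract_matrix_batch(tracks, windows: Sequence[GenomicInterval],
                         panel: Optional[AssayPanel] = None,
                         bin_size: int = BIN_SIZE) -> np.ndarray:
    """Vectorised extraction: (n_windows, 5, n_bins) float32 array."""
    panel = panel or AssayPanel()
    by_assay = _tracks_by_assay(tracks)
    missing = [a for a in panel.assays if a not in by_assay]
    if missing:
        raise KeyError(f"missing tracks for assays {missing}")
    n_bins = WINDOW_SIZE // bin_size
    out = np.zeros((len(windows), N_ASSAYS, n_bins), dtype=np.float32)
    for i, win in enumerate(windows):
        for r, assay in enumerate(panel.assays):
            out[i, r] = bin_signal(by_assay[assay], win, bin_size)
    return out


def sliding_windows(chrom_length: int, window: int = WINDOW_SIZE,
                    step: int = STEP_SIZE, chrom: str = "chr") -> list:
    """Fixed-size windows tiling [0, chrom_length) at the given stride.

    Starts at 0, step, 2*step, ...; windows that would extend past the
    chromosome end are dropped (not clipped), preserving the matrix shape.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    return [GenomicInterval(chrom, s, s + window)
            for s in range(0, chrom_length - window + 1, step)]
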