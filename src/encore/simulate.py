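"""Synthetic five-assay epigenomes with planted enhancers and known cores.

The generator emulates the canonical active-enhancer signal architecture:
a unimodal chromatin-accessibility peak over the nucleosome-depleted core,
and a peak-trough-peak profile in the active histone marks — flanking
nucleosome peaks outside the core with a dip over it — on top of smooth,
non-negative, coverage-like background noise.  Ground-truth core intervals
are returned for boundary-recovery evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d

from .labeling import DEFAULT_NEGATIVE_RATIO, LabeledDataset, sample_negatives
from .signal_io import (AssayPanel, GenomicInterval, SignalTrack, WINDOW_SIZE,
                        extract_matrix_batch)

__all__ = ["SimConfig", "GroundTruth", "simulate_tracks", "simulate_dataset"]

# enhancers range roughly 50-1500 bp; the simulator plants cores in that span
ENHANCER_LENGTH_RANGE = (50, 1500)


@dataclass
class SimConfig:
    """Synthetic-genome configuration.

    Defaults define the standard study conditions: 1:10 class imbalance,
    enhancer cores drawn uniformly from 50-1500 bp, accessibility bumps of
    amplitude 4 over a background of ~1, histone flank peaks of amplitude 3
    centred 100 bp outside the core edges (the +1/-1 nucleosomes hugging the
    accessible core) with a 60% trough over the core, lognormal background
    noise of scale 0.5 smoothed over 50 bp, and positive windows jittered up
    to +/-500 bp off the core centre.
    """

    n_positive: int = 100
    neg_ratio: int = DEFAULT_NEGATIVE_RATIO
    chrom_length: int = 500_000
    n_chroms: Optional[int] = None          # None: smallest number that fits
    enhancer_length_range: tuple = ENHANCER_LENGTH_RANGE
    accessibility_amplitude: float = 4.0
    histone_amplitude: float = 3.0
    trough_depth: float = 0.6               # fractional dip of background in core
    flank_offset: int = 100                 # bp outside the core edge, peak centre
    flank_sigma: float = 60.0               # bp, width of histone flank peaks
    noise_scale: float = 0.5                # sigma of log-background noise
    noise_smooth: int = 50                  # bp moving-average of the background
    window: int = WINDOW_SIZE
    center_offset: int = 500                # max |offset| of window centre vs core
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.enhancer_length_range
        if lo < ENHANCER_LENGTH_RANGE[0] or hi > ENHANCER_LENGTH_RANGE[1]:
            raise ValueError(
                f"enhancer lengths must lie within {ENHANCER_LENGTH_RANGE}")
        if lo > hi:
            raise ValueError("invalid enhancer length range")
        if self.accessibility_amplitude <= 0 or self.histone_amplitude <= 0:
            raise ValueError("amplitudes must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be >= 0")
        if not 0.0 <= self.trough_depth <= 1.0:
            raise ValueError("trough depth is a fraction in [0, 1]")


@dataclass
class GroundTruth:
    """Planted enhancer cores and the per-enhancer parameters used."""

    intervals: list                          # core GenomicIntervals
    chrom_sizes: dict
    params: list = field(default_factory=list)
    positive_windows: list = field(default_factory=list)


def _slot_size(cfg: SimConfig) -> int:
    # one enhancer per slot; window + jitter + flanks must fit with margin
    return cfg.window + 2 * cfg.center_offset + 2 * cfg.flank_offset + 2000


def _place_enhancers(cfg: SimConfig, rng) -> GroundTruth:
    slot = _slot_size(cfg)
    margin = cfg.window
    per_chrom = (cfg.chrom_length - 2 * margin) // slot
    if per_chrom < 1:
        raise ValueError("chromosome too short for even one enhancer slot")
    n_chroms = cfg.n_chroms
    if n_chroms is None:
        n_chroms = -(-cfg.n_positive // per_chrom)
    elif n_chroms * per_chrom < cfg.n_positive:
        raise ValueError(
            f"{cfg.n_positive} enhancers do not fit in {n_chroms} chromosomes "
            f"of {cfg.chrom_length} bp ({per_chrom} slots each)")
    sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(n_chroms)}
    lo, hi = cfg.enhancer_length_range
    intervals, params = [], []
    placed = 0
    jitter_max = max(1, slot - cfg.window - 2 * cfg.center_offset
                     - 2 * cfg.flank_offset - 1000)
    for chrom in sizes:
        for i in range(per_chrom):
            if placed == cfg.n_positive:
                break
            length = int(rng.integers(lo, hi + 1))
            jitter = int(rng.integers(0, jitter_max))
            center = margin + i * slot + slot // 2 + jitter - jitter_max // 2
            start = center - length // 2
            intervals.append(GenomicInterval(chrom, start, start + length))
            params.append({"length": length, "center": center})
            placed += 1
    return GroundTruth(intervals=intervals, chrom_sizes=sizes, params=params)


def _add_bump(arr: np.ndarray, center: int, sigma: float, amplitude: float
              ) -> None:
    """Add a Gaussian bump truncated at 4 sigma, in place."""
    lo = max(0, int(center - 4 * sigma))
    hi = min(len(arr), int(center + 4 * sigma) + 1)
    if hi <= lo:
        return
    x = np.arange(lo, hi, dtype=np.float64)
    arr[lo:hi] += amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _background(length: int, cfg: SimConfig, rng) -> np.ndarray:
    if cfg.noise_scale == 0:
        return np.ones(length, dtype=np.float32)
    noise = np.exp(rng.normal(0.0, cfg.noise_scale, length)
                   .astype(np.float32))
    return uniform_filter1d(noise, cfg.noise_smooth, mode="nearest")


def simulate_tracks(config: SimConfig
                    ) -> tuple[list, GroundTruth]:
    """Generate the five co-registered signal tracks plus ground truth.

    Returns tracks in default panel order.  Accessibility carries a single
    smooth bump centred on each core (sigma = core length / 4); each histone
    mark carries two flank bumps outside the core and a multiplicative
    trough over it.  All values are finite and >= 0; same seed, same tracks.
    """
    rng = np.random.default_rng(config.seed)
    truth = _place_enhancers(config, rng)
    panel = AssayPanel()
    tracks = [SignalTrack(assay=a) for a in panel.assays]
    acc_row = panel.accessibility_row
    # per-histone amplitude wobble so the five marks are not identical
    hist_gain = {r: 0.7 + 0.6 * rng.random() for r in range(5) if r != acc_row}
    for chrom, L in truth.chrom_sizes.items():
        arrays = [_background(L, config, rng).astype(np.float64)
                  for _ in range(5)]
        cores = [iv for iv in truth.intervals if iv.chrom == chrom]
        for iv in cores:
            center = (iv.start + iv.end) // 2
            core_len = len(iv)
            _add_bump(arrays[acc_row], center, core_len / 4.0,
                      config.accessibility_amplitude)
            left = iv.start - config.flank_offset
            right = iv.end + config.flank_offset
            trough_sigma = core_len / 2.0
            lo = max(0, int(center - 4 * trough_sigma))
            hi = min(L, int(center + 4 * trough_sigma) + 1)
            x = np.arange(lo, hi, dtype=np.float64)
            dip = 1.0 - config.trough_depth * np.exp(
                -0.5 * ((x - center) / trough_sigma) ** 2)
            for r, gain in hist_gain.items():
                arrays[r][lo:hi] *= dip
                amp = config.histone_amplitude * gain
                _add_bump(arrays[r], left, config.flank_sigma, amp)
                _add_bump(arrays[r], right, config.flank_sigma, amp)
        for r in range(5):
            tracks[r].values[chrom] = np.maximum(
                arrays[r], 0.0).astype(np.float32)
    return tracks, truth


def simulate_dataset(config: SimConfig
                     ) -> tuple[LabeledDataset, GroundTruth]:
    """Labeled 4 kb windows from a simulated genome.

    Positive windows are centred on each core with a uniform offset in
    [-center_offset, +center_offset]; negatives are sampled from the
    background (excluding all positive windows) at `neg_ratio` per positive.
    """
    rng = np.random.default_rng(config.seed)
    tracks, truth = simulate_tracks(config)
    half = config.window // 2
    positives = []
    for iv in truth.intervals:
        off = int(rng.integers(-config.center_offset, config.center_offset + 1)
                  ) if config.center_offset else 0
        center = (iv.start + iv.end) // 2 + off
        start = min(max(center - half, 0),
                    truth.chrom_sizes[iv.chrom] - config.window)
        positives.append(GenomicInterval(iv.chrom, start, start + config.window))
    truth.positive_windows = positives
    negatives = sample_negatives(
        truth.chrom_sizes, positives, ratio=config.neg_ratio,
        seed=int(rng.integers(0, 2**31)), window=config.window)
    windows = positives + negatives
    X = extract_matrix_batch(tracks, windows)
    y = np.concatenate([np.ones(len(positives), dtype=np.int8),
                        np.zeros(len(negatives), dtype=np.int8)])
    chrom = np.array([w.chrom for w in windows])
    ct = np.full(len(windows), "synthetic")
    ds = LabeledDataset(X=X, y=y, chrom=chrom, cell_type=ct, windows=windows,
                        metadata={"seed": config.seed,
                                  "config": asdict(config)})
    return ds, truth
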