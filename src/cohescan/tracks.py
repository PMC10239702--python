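"""Binned 1D signal tracks (PC1, insulation score, methylation, mutation
density) and site-anchored aggregate profiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cohescan.genome import midpoints


@dataclass
class SignalTrack:
    """Uniformly binned per-chromosome signal; NaN marks a missing bin."""

    chrom: str
    bin_size: int
    values: np.ndarray
    start_offset: int = 0

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def span(self) -> tuple[int, int]:
        return self.start_offset, self.start_offset + self.n_bins * self.bin_size

    def bin_index(self, pos: int) -> int | None:
        """Bin covering position ``pos``; None when outside the span."""
        i = (pos - self.start_offset) // self.bin_size
        return int(i) if 0 <= i < self.n_bins else None

    def value_at(self, pos: int) -> float:
        i = self.bin_index(pos)
        return float(self.values[i]) if i is not None else float("nan")


@dataclass
class ProfileMatrix:
    """Per-site signal at signed offsets from the site midpoint."""

    site_ids: list
    offsets: np.ndarray  # signed bp, bin centers, strictly increasing
    values: np.ndarray  # sites x offsets

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if not np.allclose(self.offsets, -self.offsets[::-1]):
            raise ValueError("offsets must be symmetric about 0")

    def mean_profile(self) -> np.ndarray:
        """Column means over sites, ignoring missing bins."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)


def mean_track(tracks: list[SignalTrack]) -> SignalTrack:
    """Element-wise nan-mean of replicate tracks on the same grid."""
    first = tracks[0]
    for t in tracks[1:]:
        if (t.chrom, t.bin_size, t.start_offset, t.n_bins) != (
            first.chrom,
            first.bin_size,
            first.start_offset,
            first.n_bins,
        ):
            raise ValueError("replicate tracks are not on a common grid")
    stack = np.vstack([t.values for t in tracks])
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(stack, axis=0)
    return SignalTrack(first.chrom, first.bin_size, avg, first.start_offset)


def aggregate_signal_profile(
    sites: pd.DataFrame,
    tracks: SignalTrack | dict[str, SignalTrack],
    flank_bp: int,
    bin_bp: int,
) -> ProfileMatrix:
    """Site-anchored aggregation of a binned track.

    Row s, column o holds the mean of the track bins whose centers fall in
    the profile bin at offset o from site s's midpoint.  Sites outside the
    track span (or profile bins with no covered track bin) are NaN, never
    silently dropped.
    """
    if flank_bp % bin_bp:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    if isinstance(tracks, SignalTrack):
        tracks = {tracks.chrom: tracks}
    n_bins = 2 * flank_bp // bin_bp
    offsets = -flank_bp + bin_bp * np.arange(n_bins) + bin_bp // 2
    out = np.full((len(sites), n_bins), np.nan)
    mids = midpoints(sites)
    for row, (chrom, m) in enumerate(zip(sites["chrom"], mids)):
        track = tracks.get(chrom)
        if track is None:
            continue
        centers = track.start_offset + track.bin_size * np.arange(track.n_bins) + track.bin_size // 2
        for col in range(n_bins):
            lo = m - flank_bp + col * bin_bp
            in_bin = (centers >= lo) & (centers < lo + bin_bp)
            if in_bin.any():
                vals = track.values[in_bin]
                if np.isfinite(vals).any():
                    out[row, col] = np.nanmean(vals)
    ids = list(sites["name"]) if "name" in sites.columns else list(sites.index)
    return ProfileMatrix(ids, offsets, out)


def counts_track(positions: np.ndarray, chrom: str, chrom_len: int, bin_size: int) -> SignalTrack:
    """Per-bin counts of point events (e.g. mutations) on one chromosome."""
    n = int(np.ceil(chrom_len / bin_size))
    counts = np.bincount((np.asarray(positions, dtype=np.int64) // bin_size), minlength=n)[:n]
    return SignalTrack(chrom, bin_size, counts.astype(float))
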