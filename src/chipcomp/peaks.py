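"""Peak calling by the mean + 2·SD cutoff.

The cutoff is computed per sequencing sample over all of its percent-
normalized probe values (sample SD, n−1 denominator); probes strictly above
the cutoff are candidate peaks, and maximal runs of consecutive candidate
probes are merged into peak intervals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .occupancy import ProbeTrack


def compute_cutoff(track: ProbeTrack, multiplier: float = 2.0) -> tuple[float, float, float]:
    """Mean, sample SD, and cutoff = mean + multiplier·SD of a track."""
    values = np.asarray(track.percent, dtype=np.float64)
    if len(values) < 2:
        raise ValueError("cutoff needs at least 2 probes")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    return mean, sd, mean + multiplier * sd


def call_candidates(track: ProbeTrack, cutoff: float) -> np.ndarray:
    """Indices of probes strictly above the cutoff, ascending.

    Ties at the cutoff are background.
    """
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    return np.flatnonzero(np.asarray(track.percent) > cutoff)


def merge_candidates(candidates: np.ndarray, probes: np.ndarray) -> list[tuple[int, int]]:
    """Merge maximal runs of consecutive candidate indices into intervals."""
    candidates = np.asarray(candidates, dtype=np.int64)
    if len(candidates) == 0:
        return []
    if np.any(np.diff(candidates) <= 0):
        raise ValueError("candidate indices must be sorted ascending and unique")
    probes = np.asarray(probes)
    breaks = np.flatnonzero(np.diff(candidates) > 1)
    run_starts = np.concatenate(([0], breaks + 1))
    run_ends = np.concatenate((breaks, [len(candidates) - 1]))
    return [
        (int(probes[candidates[a], 0]), int(probes[candidates[b], 1]))
        for a, b in zip(run_starts, run_ends)
    ]


@dataclass
class PeakCall:
    """Per-sample cutoff, candidate probes, and merged peak intervals."""

    mean: float
    sd: float
    cutoff: float
    candidate_probes: np.ndarray
    peaks: list[tuple[int, int]]
    peak_max_percent: list[float]

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_probes)


def call_peaks(track: ProbeTrack, multiplier: float = 2.0) -> PeakCall:
    """Cutoff → candidates → merged peaks for one sample."""
    mean, sd, cutoff = compute_cutoff(track, multiplier)
    candidates = call_candidates(track, cutoff)
    probes = track.probes
    peaks = merge_candidates(candidates, probes)
    maxima = []
    for start, end in peaks:
        lo = np.searchsorted(probes[:, 0], start)
        hi = np.searchsorted(probes[:, 0], end)
        maxima.append(float(np.max(track.percent[lo:hi])))
    return PeakCall(
        mean=mean,
        sd=sd,
        cutoff=cutoff,
        candidate_probes=candidates,
        peaks=peaks,
        peak_max_percent=maxima,
    )
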