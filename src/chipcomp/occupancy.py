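"""Fixed-width probe quantitation and percent normalization.

The genome is tiled into fixed-width probes (50 bp by default), each read
increments every probe its interval overlaps by at least one base, and probe
values are normalized to percent of the total uniquely mapped reads of that
sample.  Because a 300–500 bp fragment spans several 50 bp probes, the probe
percents sum to more than 100; the denominator is deliberately the read
total, not the contribution total.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .models import AlignedRead, GenomeModel

log = logging.getLogger(__name__)

DEFAULT_PROBE_WIDTH = 50


def tile_probes(genome_length: int, probe_width: int = DEFAULT_PROBE_WIDTH) -> np.ndarray:
    """Tile ``[0, genome_length)`` into consecutive fixed-width intervals.

    Returns an ``(n, 2)`` int array of half-open intervals; the final probe
    is truncated at the genome end so the tiling is exact.
    """
    if genome_length <= 0:
        raise ValueError(f"genome_length must be > 0, got {genome_length}")
    if probe_width <= 0:
        raise ValueError(f"probe_width must be > 0, got {probe_width}")
    n = -(-genome_length // probe_width)  # ceil
    starts = np.arange(n, dtype=np.int64) * probe_width
    ends = np.minimum(starts + probe_width, genome_length)
    return np.stack([starts, ends], axis=1)


def _read_arrays(reads: Iterable[AlignedRead]) -> tuple[np.ndarray, np.ndarray]:
    pairs = [(r.start, r.end) for r in reads if r.unique]
    if not pairs:
        return (np.empty(0, dtype=np.int64),) * 2
    arr = np.asarray(pairs, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def count_reads(probes: np.ndarray, reads: Iterable[AlignedRead]) -> np.ndarray:
    """Per-probe read counts under the any-overlap rule.

    A read increments every probe it overlaps by >=1 bp.  Only reads flagged
    unique are counted.  Reads must lie within the tiled genome; on a
    circular genome, junction-spanning fragments are expected to have been
    split into linear sub-intervals upstream.
    """
    probes = np.asarray(probes)
    if probes.ndim != 2 or probes.shape[1] != 2 or len(probes) == 0:
        raise ValueError("probes must be a non-empty (n, 2) interval array")
    width = int(probes[0, 1] - probes[0, 0])
    genome_length = int(probes[-1, 1])
    expected = tile_probes(genome_length, width)
    if expected.shape != probes.shape or not np.array_equal(expected, probes):
        raise ValueError("probes must be a contiguous fixed-width tiling")

    starts, ends = _read_arrays(reads)
    n = len(probes)
    counts = np.zeros(n, dtype=np.int64)
    if len(starts) == 0:
        return counts
    if starts.min() < 0 or ends.max() > genome_length:
        i = int(np.argmax((starts < 0) | (ends > genome_length)))
        raise ValueError(
            f"read [{starts[i]}, {ends[i]}) outside genome [0, {genome_length}); "
            "split junction-spanning reads before counting"
        )
    first = starts // width
    last = (ends - 1) // width
    # difference-array accumulation: +1 at first probe, -1 past the last
    diff = np.zeros(n + 1, dtype=np.int64)
    np.add.at(diff, first, 1)
    np.add.at(diff, last + 1, -1)
    counts = np.cumsum(diff)[:-1]
    return counts


def total_unique_reads(reads: Iterable[AlignedRead]) -> int:
    """Number of distinct unique reads (split fragment halves share a name
    and count once; anonymous reads count individually)."""
    names: set[str] = set()
    anonymous = 0
    for r in reads:
        if not r.unique:
            continue
        if r.name is None:
            anonymous += 1
        else:
            names.add(r.name)
    return anonymous + len(names)


def percent_normalize(counts: np.ndarray, total: int) -> np.ndarray:
    """Percent of total uniquely mapped reads per probe.

    ``percent[i] = 100 * counts[i] / total``; a zero total yields an
    all-zero track with a logged warning rather than an error.
    """
    counts = np.asarray(counts)
    if total < 0:
        raise ValueError(f"total_unique_reads must be >= 0, got {total}")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if total == 0:
        log.warning("total_unique_reads is 0; percent track set to all zeros")
        return np.zeros(len(counts), dtype=np.float64)
    return 100.0 * counts.astype(np.float64) / float(total)


@dataclass
class ProbeTrack:
    """One sample's quantified probe grid.

    The probe intervals are implicit in (genome_length, probe_width): probe
    ``i`` is ``[i*w, min((i+1)*w, L))``.
    """

    genome_name: str
    genome_length: int
    probe_width: int
    counts: np.ndarray
    total_unique_reads: int
    percent: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = -(-self.genome_length // self.probe_width)
        if len(self.counts) != n:
            raise ValueError(
                f"expected {n} probes for length {self.genome_length} at width "
                f"{self.probe_width}, got {len(self.counts)}"
            )
        if self.percent is None:
            self.percent = percent_normalize(self.counts, self.total_unique_reads)
        else:
            self.percent = np.asarray(self.percent, dtype=np.float64)

    @property
    def n_probes(self) -> int:
        return len(self.counts)

    @property
    def probes(self) -> np.ndarray:
        return tile_probes(self.genome_length, self.probe_width)

    @property
    def starts(self) -> np.ndarray:
        return self.probes[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.probes[:, 1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeTrack):
            return NotImplemented
        return (
            self.genome_name == other.genome_name
            and self.genome_length == other.genome_length
            and self.probe_width == other.probe_width
            and self.total_unique_reads == other.total_unique_reads
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.percent, other.percent)
        )


def quantify(
    genome: GenomeModel,
    reads: Sequence[AlignedRead],
    probe_width: int = DEFAULT_PROBE_WIDTH,
) -> ProbeTrack:
    """Full quantitation for one sample: tile, count, percent-normalize."""
    probes = tile_probes(genome.length, probe_width)
    counts = count_reads(probes, reads)
    total = total_unique_reads(reads)
    return ProbeTrack(
        genome_name=genome.name,
        genome_length=genome.length,
        probe_width=probe_width,
        counts=counts,
        total_unique_reads=total,
    )
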