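"""Synthetic comparative ChIP experiment with known planted enrichment.

Generates a small circular bacterial genome with non-overlapping genes on
both strands, and per-condition IP read sets drawn from a mixture of uniform
genomic background and fold-enriched loci.  Fragment midpoints carry the
enrichment (ChIP signal is symmetric about the bound site); fragment lengths
are uniform on the sonication target range of 300–500 bp.  Everything is a
pure function of (config, seed): identical inputs give bit-identical output,
one RNG stream per (seed, condition).
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import AlignedRead, GeneModel, GenomeModel

DEFAULT_FRAGMENT_RANGE = (300, 500)
DEFAULT_CONDITIONS = ("wt", "mutant")


@dataclass(frozen=True)
class EnrichmentSpec:
    """One planted locus: fragments whose midpoints fall in
    ``[center - half_width, center + half_width)`` are oversampled by
    ``fold`` relative to background (fold 1 = background)."""

    locus_id: str
    locus_center: int
    half_width: int
    fold_by_condition: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        for cond, fold in self.fold_by_condition.items():
            if not (math.isfinite(fold) and fold >= 1.0):
                raise ValueError(
                    f"fold for condition {cond!r} must be finite and >= 1, "
                    f"got {fold}"
                )

    @property
    def width(self) -> int:
        return 2 * self.half_width

    def window(self) -> tuple[int, int]:
        """Midpoint window [center - hw, center + hw), un-normalized (may
        extend past genome bounds on a circular genome)."""
        return self.locus_center - self.half_width, self.locus_center + self.half_width

    @property
    def is_background(self) -> bool:
        return all(f == 1.0 for f in self.fold_by_condition.values())


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic comparative experiment."""

    genome_length: int = 200_000
    n_genes: int = 50
    n_reads_per_condition: int = 100_000
    fragment_length_range: tuple[int, int] = DEFAULT_FRAGMENT_RANGE
    enrichments: tuple[EnrichmentSpec, ...] = ()
    seed: int = 0
    genome_name: str = "synthetic_chr"
    circular: bool = True
    gene_length_range: tuple[int, int] = (600, 1500)
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        lo, hi = self.fragment_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad fragment_length_range {self.fragment_length_range}")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        for spec in self.enrichments:
            lo_w, hi_w = spec.window()
            if not self.circular and not (0 <= lo_w and hi_w <= self.genome_length):
                raise ValueError(
                    f"enrichment {spec.locus_id} window [{lo_w}, {hi_w}) "
                    "outside linear genome"
                )
            if spec.width > self.genome_length:
                raise ValueError(f"enrichment {spec.locus_id} wider than genome")


def _stream(seed: int, label: str) -> np.random.Generator:
    """One independent, deterministic RNG stream per (seed, label)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def make_genome(config: SimulationConfig) -> GenomeModel:
    """Place non-overlapping genes of random length on random strands.

    Deterministic under the config seed.  Placement distributes the spare
    space between genes uniformly at random; an infeasible configuration
    (genes cannot fit) is a hard error.
    """
    rng = _stream(config.seed, "genome")
    if config.n_genes == 0:
        return GenomeModel(
            name=config.genome_name, length=config.genome_length,
            circular=config.circular, genes=[],
        )
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    spare = config.genome_length - int(lengths.sum())
    if spare < config.n_genes:
        raise ValueError(
            f"cannot place {config.n_genes} genes of total length "
            f"{int(lengths.sum())} in a {config.genome_length} bp genome"
        )
    offsets = np.sort(rng.choice(spare, size=config.n_genes, replace=False))
    starts = offsets + np.concatenate(([0], np.cumsum(lengths)[:-1]))
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)
    genes = [
        GeneModel(
            gene_id=f"gene{i + 1:04d}",
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
            strand=str(strands[i]),
        )
        for i in range(config.n_genes)
    ]
    return GenomeModel(
        name=config.genome_name, length=config.genome_length,
        circular=config.circular, genes=genes,
    )


def _fragment_to_reads(
    name: str, start: int, end: int, genome: GenomeModel, reference: str
) -> list[AlignedRead]:
    """Normalize a raw fragment interval to linear sub-intervals.

    Circular genomes wrap: a junction-spanning fragment becomes two reads
    that share the fragment name.  Linear genomes clip at the boundaries.
    """
    L = genome.length
    if genome.circular:
        length = end - start
        start %= L
        end = start + length
        if end <= L:
            return [AlignedRead(reference, start, end, name=name)]
        return [
            AlignedRead(reference, start, L, name=name),
            AlignedRead(reference, 0, end - L, name=name),
        ]
    start = max(start, 0)
    end = min(end, L)
    return [AlignedRead(reference, start, end, name=name)]


def simulate_reads(
    genome: GenomeModel, config: SimulationConfig, condition: str
) -> list[AlignedRead]:
    """Draw one condition's IP reads from the background/enrichment mixture.

    Midpoint density is uniform at rate 1 over the genome plus an extra
    ``(fold - 1)`` over each enriched window, so the expected probe-level
    enrichment inside a window is exactly its fold.  Fragment lengths are
    uniform integers on the configured range.  All reads are unique.
    """
    for spec in config.enrichments:
        if condition not in spec.fold_by_condition:
            raise ValueError(
                f"condition {condition!r} missing from enrichment "
                f"{spec.locus_id} fold map"
            )
    n = config.n_reads_per_condition
    if n == 0:
        return []
    rng = _stream(config.seed, f"reads:{condition}")
    L = genome.length

    specs = list(config.enrichments)
    extra = np.array(
        [(s.fold_by_condition[condition] - 1.0) * s.width for s in specs],
        dtype=np.float64,
    )
    masses = np.concatenate(([float(L)], extra))
    weights = masses / masses.sum()
    component = rng.choice(len(masses), size=n, p=weights)

    midpoints = np.empty(n, dtype=np.int64)
    background = component == 0
    midpoints[background] = rng.integers(0, L, size=int(background.sum()))
    for i, spec in enumerate(specs, start=1):
        mask = component == i
        k = int(mask.sum())
        if k:
            lo, hi = spec.window()
            midpoints[mask] = rng.integers(lo, hi, size=k)

    frag_lo, frag_hi = config.fragment_length_range
    lengths = rng.integers(frag_lo, frag_hi + 1, size=n)
    starts = midpoints - lengths // 2
    ends = starts + lengths

    reads: list[AlignedRead] = []
    for i in range(n):
        reads.extend(
            _fragment_to_reads(
                f"{condition}_{i:07d}", int(starts[i]), int(ends[i]),
                genome, genome.name,
            )
        )
    return reads


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth table: one row per (enrichment locus × condition).

    ``footprint_start/end`` extend the midpoint window by half the maximum
    fragment length on each side — the full span enriched fragments can
    cover, used when scoring called peak bases against the planted truth.
    Pure function of the config (no RNG).
    """
    pad = config.fragment_length_range[1] // 2
    rows = []
    for spec in config.enrichments:
        lo, hi = spec.window()
        for condition in config.conditions:
            rows.append(
                {
                    "locus_id": spec.locus_id,
                    "locus_center": spec.locus_center,
                    "half_width": spec.half_width,
                    "window_start": lo,
                    "window_end": hi,
                    "footprint_start": lo - pad,
                    "footprint_end": hi + pad,
                    "condition": condition,
                    "expected_fold": float(spec.fold_by_condition[condition]),
                    "background": spec.is_background,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "locus_center", "half_width", "window_start",
            "window_end", "footprint_start", "footprint_end", "condition",
            "expected_fold", "background",
        ],
    )


def linear_intervals(lo: int, hi: int, genome_length: int, circular: bool = True) -> list[tuple[int, int]]:
    """Express a raw half-open window (possibly out of bounds) as linear
    intervals within [0, L): wrapped windows split in two, linear genomes
    clip.  Used when comparing planted windows with called peaks."""
    L = genome_length
    width = hi - lo
    if width <= 0:
        return []
    if width >= L:
        return [(0, L)]
    if not circular:
        lo, hi = max(lo, 0), min(hi, L)
        return [(lo, hi)] if lo < hi else []
    lo %= L
    hi = lo + width
    if hi <= L:
        return [(lo, hi)]
    return [(lo, L), (0, hi - L)]


def demo_scenario(
    seed: int = 0,
    genome_length: int = 200_000,
    n_genes: int = 50,
    n_reads_per_condition: int = 100_000,
) -> tuple[SimulationConfig, GenomeModel]:
    """The packaged two-condition comparison with planted ground truth.

    Three loci at fold 10 and half-width 500: two promoter-proximal loci
    (one per strand, centered in the −500/+100 window of a real gene),
    enriched equally in both conditions, and one origin-like locus in the
    largest intergenic gap that is enriched only in the ``mutant``
    condition — the planted differential target.
    """
    base = SimulationConfig(
        genome_length=genome_length,
        n_genes=n_genes,
        n_reads_per_condition=n_reads_per_condition,
        seed=seed,
    )
    genome = make_genome(base)
    plus = [g for g in genome.genes if g.strand == "+"]
    minus = [g for g in genome.genes if g.strand == "-"]
    if not plus or not minus:
        raise ValueError("demo scenario needs genes on both strands")
    gene_a = plus[len(plus) // 2]
    gene_b = minus[len(minus) // 2]
    # promoter-window midpoint: 200 bp upstream of the TSS, strand-aware
    center_a = gene_a.tss - 200
    center_b = gene_b.tss + 200

    # origin-like locus: middle of the largest gap between gene bodies
    bounds = sorted((g.start, g.end) for g in genome.genes)
    gaps = []
    for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
        gaps.append((s2 - e1, e1, s2))
    gaps.append((genome_length - bounds[-1][1] + bounds[0][0],
                 bounds[-1][1], bounds[0][0] + genome_length))
    width, gap_lo, gap_hi = max(gaps)
    ori_center = ((gap_lo + gap_hi) // 2) % genome_length

    half_width = 500
    enrichments = (
        EnrichmentSpec("ori_like", ori_center, half_width,
                       {"wt": 1.0, "mutant": 10.0}),
        EnrichmentSpec(f"promoter_{gene_a.gene_id}", center_a, half_width,
                       {"wt": 10.0, "mutant": 10.0}),
        EnrichmentSpec(f"promoter_{gene_b.gene_id}", center_b, half_width,
                       {"wt": 10.0, "mutant": 10.0}),
    )
    config = replace(base, enrichments=enrichments)
    return config, genome
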