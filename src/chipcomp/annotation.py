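"""Strand-aware promoter-window annotation of candidate probes.

A probe is assigned to a gene when the probe's center falls within −500/+100
bases of the gene's transcription start site, oriented by the gene's strand
(upstream is 5' of the TSS).  A probe may satisfy the rule for two genes on
opposite strands (divergent promoters) — both are reported.  Probes matching
no promoter window are labeled ``NO ANNO``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .models import GeneModel, GenomeModel

NO_ANNO = "NO ANNO"
DEFAULT_UPSTREAM = 500
DEFAULT_DOWNSTREAM = 100


def probe_center(probe: tuple[int, int]) -> int:
    """Center base of a probe; for even widths, the left of the two middle
    bases (deterministic integer convention)."""
    start, end = int(probe[0]), int(probe[1])
    if start >= end:
        raise ValueError(f"invalid probe [{start}, {end})")
    return (start + end - 1) // 2


def promoter_window(
    gene: GeneModel,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    genome_length: int | None = None,
    circular: bool = False,
) -> tuple[int, int]:
    """Closed (inclusive) promoter interval around the TSS, strand-oriented.

    + strand: ``[tss - upstream, tss + downstream]``; − strand the mirror
    image.  On a linear genome the window is clipped to ``[0, L-1]``; on a
    circular genome it wraps (a returned ``lo > hi`` means the window spans
    the origin junction).
    """
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - upstream, tss + downstream
    else:
        lo, hi = tss - downstream, tss + upstream
    if genome_length is None:
        return lo, hi
    if circular:
        return lo % genome_length, hi % genome_length
    return max(lo, 0), min(hi, genome_length - 1)


def _window_contains(lo: int, hi: int, pos: int) -> bool:
    if lo <= hi:
        return lo <= pos <= hi
    return pos >= lo or pos <= hi  # wrapped window


def _tss_distance(center: int, tss: int, length: int, circular: bool) -> int:
    d = abs(center - tss)
    if circular:
        d = min(d, length - d)
    return d


@dataclass(frozen=True)
class AnnotationRecord:
    """Assignment of one probe to 0–2 genes (two only for a divergent pair)."""

    probe: tuple[int, int]
    probe_center: int
    gene_ids: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        if len(self.gene_ids) > 2:
            raise ValueError("at most two genes per probe")
        if (self.label == NO_ANNO) != (len(self.gene_ids) == 0):
            raise ValueError("label must be NO ANNO exactly when no gene matched")


def annotate_probes(
    candidates: Iterable[tuple[int, int]],
    genome: GenomeModel,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[AnnotationRecord]:
    """Annotate candidate probes against every gene's promoter window.

    When more than one gene on the same strand matches a center (dense
    genomes), the gene with the nearest TSS on that strand is reported, so a
    record carries at most one gene per strand.
    """
    tree = IntervalTree()
    for gene in genome.genes:
        lo, hi = promoter_window(gene, upstream, downstream,
                                 genome_length=genome.length,
                                 circular=genome.circular)
        if lo <= hi:
            tree.addi(lo, hi + 1, gene)
        else:  # wrapped: two linear pieces
            tree.addi(lo, genome.length, gene)
            tree.addi(0, hi + 1, gene)

    records: list[AnnotationRecord] = []
    for probe in candidates:
        probe = (int(probe[0]), int(probe[1]))
        center = probe_center(probe)
        hits = {iv.data for iv in tree.at(center)}
        chosen: list[GeneModel] = []
        for strand in ("+", "-"):
            on_strand = [g for g in hits if g.strand == strand]
            if on_strand:
                chosen.append(
                    min(
                        on_strand,
                        key=lambda g: (
                            _tss_distance(center, g.tss, genome.length,
                                          genome.circular),
                            g.tss,
                            g.gene_id,
                        ),
                    )
                )
        gene_ids = tuple(g.gene_id for g in chosen)
        label = ",".join(gene_ids) if gene_ids else NO_ANNO
        records.append(
            AnnotationRecord(probe=probe, probe_center=center,
                             gene_ids=gene_ids, label=label)
        )
    return records


def write_annotation_table(
    records: Sequence[AnnotationRecord], path, **params
) -> None:
    """TSV export: probe coordinates, center, gene ids, label."""
    from .io_formats import parameter_header

    lines = parameter_header("annotation", **params)
    lines.append("probe_start\tprobe_end\tprobe_center\tgene_ids\tlabel")
    for rec in records:
        lines.append(
            f"{rec.probe[0]}\t{rec.probe[1]}\t{rec.probe_center}\t"
            f"{','.join(rec.gene_ids) if rec.gene_ids else '.'}\t{rec.label}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
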