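"""Core genomic value types shared by every pipeline stage.

All coordinates are 0-based half-open ``[start, end)`` on a single reference
sequence.  Conversion to/from 1-based inclusive conventions (GFF3, SAM)
happens only at the format boundary in :mod:`chipcomp.io_formats`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware transcription start site.

    The TSS is the strand-appropriate extremity of the annotated gene body:
    ``start`` for a + strand gene, ``end - 1`` (last covered base) for a
    − strand gene.
    """

    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        """Transcription start site (0-based, on the gene)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class AlignedRead:
    """One uniquely-mappable sequenced fragment interval.

    ``unique`` marks whether the aligner placed the read at a single genomic
    location; only unique reads are ever counted.  ``name`` ties together the
    two sub-intervals of a fragment that was split at the junction of a
    circular genome (both halves share the fragment's name).
    """

    reference: str
    start: int
    end: int
    strand: str = "+"
    unique: bool = True
    name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"read {self.name or ''}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )


@dataclass
class GenomeModel:
    """Reference coordinate frame plus its gene models.

    ``genes`` are kept sorted by start coordinate; gene identifiers are
    unique and every gene lies within ``[0, length)``.
    """

    name: str
    length: int
    circular: bool = False
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"genome length must be > 0, got {self.length}")
        seen: set[str] = set()
        for gene in self.genes:
            if gene.gene_id in seen:
                raise ValueError(f"duplicate gene id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            if gene.end > self.length:
                raise ValueError(
                    f"gene {gene.gene_id} [{gene.start}, {gene.end}) exceeds "
                    f"genome length {self.length}"
                )
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.gene_id))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)
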