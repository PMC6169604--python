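"""Format boundary: GFF3 gene models, BED/SAM alignments, TSV probe tables.

Internally everything is 0-based half-open.  GFF3 and SAM are 1-based
inclusive on disk; BED is already 0-based half-open.  The conversion lives
here and nowhere else.

Every file this module writes starts with ``#``-prefixed comment lines naming
the package version and the parameters used, so any stage can be re-run
standalone from its inputs.
"""
from __future__ import annotations

import logging
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import gffutils
import pysam

from .models import AlignedRead, GeneModel, GenomeModel

log = logging.getLogger(__name__)

try:
    VERSION = _pkg_version("chipcomp")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    VERSION = "0.0.0+src"


def parameter_header(stage: str, **params: object) -> list[str]:
    """Comment lines stamped at the top of every output file (no timestamps,
    so identical runs produce identical bytes)."""
    lines = [f"# chipcomp {VERSION} {stage}"]
    if params:
        lines.append("# " + " ".join(f"{k}={v}" for k, v in sorted(params.items())))
    return lines


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> GenomeModel:
    """Parse a single-sequence GFF3 into a :class:`GenomeModel`.

    Genome name and length come from the ``##sequence-region`` directive;
    circularity from an ``Is_circular=true`` attribute on a ``region``
    feature.  Gene records lacking a strand are rejected with a logged
    warning; duplicate gene IDs are a hard error.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    name = None
    length = None
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            fields = directive.split()
            if len(fields) != 4:
                raise ValueError(f"malformed directive: ##{directive}")
            name = fields[1]
            length = int(fields[3]) - int(fields[2]) + 1
            break
    if name is None or length is None:
        raise ValueError(f"{path}: missing ##sequence-region directive")

    circular = False
    for region in db.features_of_type("region"):
        flags = [v.lower() for v in region.attributes.get("Is_circular", [])]
        circular = circular or "true" in flags

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID", [])
        gene_id = ids[0] if ids else feat.id
        if feat.strand not in ("+", "-"):
            log.warning("gene %s has no strand; record rejected", gene_id)
            continue
        if gene_id in seen:
            raise ValueError(f"duplicate gene ID {gene_id!r} in {path}")
        seen.add(gene_id)
        # GFF3 is 1-based inclusive -> 0-based half-open
        genes.append(
            GeneModel(gene_id=gene_id, start=feat.start - 1, end=feat.end,
                      strand=feat.strand)
        )
    return GenomeModel(name=name, length=length, circular=circular, genes=genes)


def write_gff3(genome: GenomeModel, path: str | Path, **params: object) -> None:
    """Serialize a GenomeModel as single-sequence GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    lines += parameter_header("genome", **params)
    lines.append(f"##sequence-region {genome.name} 1 {genome.length}")
    circ = "true" if genome.circular else "false"
    lines.append(
        f"{genome.name}\tchipcomp\tregion\t1\t{genome.length}\t.\t+\t.\t"
        f"ID={genome.name};Is_circular={circ}"
    )
    for g in genome.genes:
        lines.append(
            f"{genome.name}\tchipcomp\tgene\t{g.start + 1}\t{g.end}\t.\t"
            f"{g.strand}\t.\tID={g.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Alignments (BED6 / SAM)
# ---------------------------------------------------------------------------

def _sam_is_unique(rec: pysam.AlignedSegment) -> bool:
    """Uniqueness from standard signals: secondary/supplementary flags,
    MAPQ 0, or an explicit multi-hit count tag (NH / X0 > 1)."""
    if rec.is_secondary or rec.is_supplementary:
        return False
    if rec.mapping_quality == 0:
        return False
    for tag in ("NH", "X0"):
        if rec.has_tag(tag) and int(rec.get_tag(tag)) > 1:
            return False
    return True


def read_alignments(
    path: str | Path,
    format: str,
    genome: GenomeModel | None = None,
) -> list[AlignedRead]:
    """Load mapped reads from SAM or BED into 0-based half-open intervals.

    Unmapped SAM records are dropped.  When ``genome`` is given, any record
    on a different reference name is a hard error.
    """
    fmt = format.lower()
    if fmt == "sam":
        reads = _read_sam(path)
    elif fmt == "bed":
        reads = _read_bed(path)
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    if genome is not None:
        bad = sorted({r.reference for r in reads if r.reference != genome.name})
        if bad:
            raise ValueError(
                f"{path}: reference name(s) {bad} not in genome {genome.name!r}"
            )
    return reads


def _read_sam(path: str | Path) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            reads.append(
                AlignedRead(
                    reference=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    unique=_sam_is_unique(rec),
                    name=rec.query_name,
                )
            )
    return reads


def _read_bed(path: str | Path) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: BED line with <3 columns: {line!r}")
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "+"
            reads.append(
                AlignedRead(
                    reference=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    strand=strand,
                    unique=True,
                    name=name,
                )
            )
    return reads


def write_bed(
    intervals,
    path: str | Path,
    stage: str = "intervals",
    **params: object,
) -> None:
    """Write AlignedReads or (start, end, score) tuples as BED6."""
    lines = parameter_header(stage, **params)
    for item in intervals:
        if isinstance(item, AlignedRead):
            lines.append(
                f"{item.reference}\t{item.start}\t{item.end}\t"
                f"{item.name or '.'}\t0\t{item.strand}"
            )
        else:
            ref, start, end, name, score = item
            lines.append(f"{ref}\t{start}\t{end}\t{name}\t{score:.17g}\t+")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Probe tables (TSV)
# ---------------------------------------------------------------------------

def write_probe_table(track, path: str | Path, **params: object) -> None:
    """Export one sample's quantified probe list as TSV.

    Percent values are serialized with 17 significant digits so the
    write→read round trip is bit-exact.
    """
    from .occupancy import ProbeTrack  # local import to avoid a cycle

    assert isinstance(track, ProbeTrack)
    lines = parameter_header(
        "probe_table",
        genome=track.genome_name,
        genome_length=track.genome_length,
        probe_width=track.probe_width,
        total_unique_reads=track.total_unique_reads,
        **params,
    )
    lines.append("probe_start\tprobe_end\tcount\tpercent")
    starts, ends = track.starts, track.ends
    for i in range(track.n_probes):
        lines.append(
            f"{starts[i]}\t{ends[i]}\t{track.counts[i]}\t{track.percent[i]:.17g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_probe_table(path: str | Path):
    """Re-load a probe table written by :func:`write_probe_table`."""
    import numpy as np

    from .occupancy import ProbeTrack

    meta: dict[str, str] = {}
    counts: list[int] = []
    percent: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
                continue
            if not line or line.startswith("probe_start"):
                continue
            cols = line.split("\t")
            counts.append(int(cols[2]))
            percent.append(float(cols[3]))
    required = ("genome", "genome_length", "probe_width", "total_unique_reads")
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValueError(f"{path}: probe table header lacks {missing}")
    track = ProbeTrack(
        genome_name=meta["genome"],
        genome_length=int(meta["genome_length"]),
        probe_width=int(meta["probe_width"]),
        counts=np.asarray(counts, dtype=np.int64),
        total_unique_reads=int(meta["total_unique_reads"]),
        percent=np.asarray(percent, dtype=np.float64),
    )
    return track
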