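#!/usr/bin/env python
"""Annotate the candidate-probe union to genes by promoter window.

A candidate probe is assigned to every gene whose strand-aware −500/+100
TSS window contains the probe center; divergent pairs report both genes,
probes with no match are labeled NO ANNO.  Writes results/chip/annotation.tsv.
"""
import argparse
from pathlib import Path

from chipcomp import annotate_probes
from chipcomp.annotation import write_annotation_table
from chipcomp.io_formats import read_gff3


def read_candidates(path: Path) -> list[tuple[int, int]]:
    probes = []
    for line in path.read_text().splitlines():
        if not line or line.startswith(("#", "probe_index")):
            continue
        cols = line.split("\t")
        probes.append((int(cols[1]), int(cols[2])))
    return probes


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
    parser.add_argument("--chipdir", type=Path, default=Path("results/chip"))
    parser.add_argument("--upstream", type=int, default=500)
    parser.add_argument("--downstream", type=int, default=100)
    args = parser.parse_args()

    genome = read_gff3(args.simdir / "genome.gff3")
    union = sorted(
        set(read_candidates(args.chipdir / "candidates_wt.tsv"))
        | set(read_candidates(args.chipdir / "candidates_mutant.tsv"))
    )
    records = annotate_probes(union, genome, upstream=args.upstream,
                              downstream=args.downstream)
    write_annotation_table(records, args.chipdir / "annotation.tsv",
                           upstream=args.upstream, downstream=args.downstream)
    by_label: dict[str, int] = {}
    for rec in records:
        by_label[rec.label] = by_label.get(rec.label, 0) + 1
    print(f"annotated {len(records)} candidate probes:")
    for label, n in sorted(by_label.items(), key=lambda kv: -kv[1]):
        print(f"  {label}: {n} probes")


if __name__ == "__main__":
    main()
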