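#!/usr/bin/env python
"""Call candidate peaks above each sample's mean + 2·SD cutoff.

Candidates are probes whose percent value strictly exceeds the cutoff;
maximal runs of consecutive candidates merge into peak intervals.  Writes
results/chip/peaks_<cond>.bed and candidates_<cond>.tsv.
"""
import argparse
from pathlib import Path

from chipcomp import call_peaks
from chipcomp.io_formats import parameter_header, read_probe_table, write_bed


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--chipdir", type=Path, default=Path("results/chip"))
    parser.add_argument("--multiplier", type=float, default=2.0)
    args = parser.parse_args()

    for condition in ("wt", "mutant"):
        track = read_probe_table(args.chipdir / f"probes_{condition}.tsv")
        call = call_peaks(track, multiplier=args.multiplier)
        write_bed(
            [(track.genome_name, s, e, f"peak{i + 1}", m)
             for i, ((s, e), m) in enumerate(zip(call.peaks, call.peak_max_percent))],
            args.chipdir / f"peaks_{condition}.bed",
            stage=f"peaks condition={condition}", cutoff=f"{call.cutoff:.17g}",
        )
        probes = track.probes
        lines = parameter_header("candidates", cutoff=f"{call.cutoff:.17g}")
        lines.append("probe_index\tprobe_start\tprobe_end\tpercent")
        for i in call.candidate_probes:
            lines.append(f"{i}\t{probes[i, 0]}\t{probes[i, 1]}\t"
                         f"{track.percent[i]:.17g}")
        (args.chipdir / f"candidates_{condition}.tsv").write_text(
            "\n".join(lines) + "\n")
        print(f"{condition}: mean={call.mean:.4f}% sd={call.sd:.4f}% "
              f"cutoff={call.cutoff:.4f}% -> {call.n_candidates} candidate "
              f"probes in {len(call.peaks)} peaks "
              f"{[(s, e) for s, e in call.peaks]}")


if __name__ == "__main__":
    main()
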