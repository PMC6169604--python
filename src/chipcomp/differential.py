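"""Comparative occupancy between two conditions: per-probe log2 ratios.

Two percent-normalized tracks on the same probe grid are paired probe-wise
and the statistic ``log2((alt + eps) / (ref + eps))`` is computed.  The
pseudocount ``eps`` defaults to the percent equivalent of a single read in
the shallower sample (``100 / min(total_reads)``), a scale-aware guard for
zero-coverage probes.  Ratios are computed as a difference of logs so that
swapping the conditions negates every value bit-exactly.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import NO_ANNO, AnnotationRecord
from .occupancy import ProbeTrack


def align_tracks(a: ProbeTrack, b: ProbeTrack) -> tuple[ProbeTrack, ProbeTrack]:
    """Validate that two tracks share one probe grid; error otherwise."""
    if a.genome_name != b.genome_name:
        raise ValueError(
            f"genome mismatch: {a.genome_name!r} vs {b.genome_name!r}"
        )
    if a.probe_width != b.probe_width:
        raise ValueError(
            f"probe width mismatch: {a.probe_width} vs {b.probe_width}"
        )
    if a.genome_length != b.genome_length or a.n_probes != b.n_probes:
        raise ValueError(
            "probe grid mismatch: first differing probe is probe 0 "
            f"(lengths {a.genome_length} vs {b.genome_length})"
        )
    return a, b


def default_epsilon(ref: ProbeTrack, alt: ProbeTrack) -> float:
    """One-read pseudocount in percent units of the shallower sample."""
    smallest = min(ref.total_unique_reads, alt.total_unique_reads)
    if smallest <= 0:
        raise ValueError(
            "cannot derive a pseudocount from an empty sample; pass epsilon"
        )
    return 100.0 / smallest


def log2_ratio(
    ref: ProbeTrack,
    alt: ProbeTrack,
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Per-probe differential table (the collection of differential records).

    Columns: probe_start, probe_end, percent_ref, percent_alt, log2_ratio.
    """
    align_tracks(ref, alt)
    if epsilon is None:
        epsilon = default_epsilon(ref, alt)
    if not (epsilon > 0):
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    probes = ref.probes
    ratio = np.log2(alt.percent + epsilon) - np.log2(ref.percent + epsilon)
    return pd.DataFrame(
        {
            "probe_start": probes[:, 0],
            "probe_end": probes[:, 1],
            "percent_ref": ref.percent,
            "percent_alt": alt.percent,
            "log2_ratio": ratio,
        }
    )


def join_annotation(
    table: pd.DataFrame, records: list[AnnotationRecord]
) -> pd.DataFrame:
    """Attach gene labels (by probe start) to a differential table."""
    labels = {rec.probe[0]: rec.label for rec in records}
    out = table.copy()
    out["gene_ids"] = [
        labels.get(int(s), NO_ANNO) for s in out["probe_start"]
    ]
    return out


def rank_targets(
    table: pd.DataFrame, candidates_union: np.ndarray
) -> pd.DataFrame:
    """Restrict to probes that are candidates in >=1 condition and rank by
    |log2 ratio| descending, ties broken by genome coordinate."""
    candidates_union = np.asarray(candidates_union, dtype=np.int64)
    subset = table.iloc[np.sort(candidates_union)].copy()
    subset["abs_log2_ratio"] = subset["log2_ratio"].abs()
    subset = subset.sort_values(
        ["abs_log2_ratio", "probe_start"],
        ascending=[False, True],
        kind="mergesort",
    ).drop(columns="abs_log2_ratio")
    return subset.reset_index(drop=True)


def write_differential_table(table: pd.DataFrame, path, **params) -> None:
    """TSV export mirroring the target-list shape: probe coords, percents,
    log2 ratio (and gene ids when annotated)."""
    from pathlib import Path

    from .io_formats import parameter_header

    lines = parameter_header("differential", **params)
    cols = list(table.columns)
    lines.append("\t".join(cols))
    for row in table.itertuples(index=False):
        fields = []
        for col, val in zip(cols, row):
            if isinstance(val, float):
                fields.append(f"{val:.17g}")
            else:
                fields.append(str(val))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
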