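"""Probe tiling, any-overlap counting, and percent normalization."""
import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chipcomp.models import AlignedRead, GenomeModel
from chipcomp.occupancy import (
    count_reads,
    percent_normalize,
    quantify,
    tile_probes,
    total_unique_reads,
)


def brute_force_counts(probes: np.ndarray, reads) -> np.ndarray:
    """All-pairs overlap scan: the independent counting oracle."""
    rs = np.array([r.start for r in reads if r.unique])
    re = np.array([r.end for r in reads if r.unique])
    if len(rs) == 0:
        return np.zeros(len(probes), dtype=np.int64)
    overlap = (probes[:, [0]] < re[None, :]) & (rs[None, :] < probes[:, [1]])
    return overlap.sum(axis=1)


def make_reads(rng, n, genome_length, max_len=400):
    starts = rng.integers(0, genome_length - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return [
        AlignedRead("chr", int(s), int(s + l), name=f"r{i}")
        for i, (s, l) in enumerate(zip(starts, lengths))
    ]


class TestTiling:
    @pytest.mark.parametrize(
        "length,width,expected_n",
        [(1000, 50, 20), (1001, 50, 21), (4_042_929, 50, 80_859), (49, 50, 1)],
    )
    def test_probe_count(self, length, width, expected_n):
        probes = tile_probes(length, width)
        assert len(probes) == expected_n
        assert probes[0, 0] == 0
        assert probes[-1, 1] == length  # final probe truncated at genome end
        assert np.all(probes[1:, 0] == probes[:-1, 1])  # gapless

    def test_truncated_final_probe(self):
        probes = tile_probes(1001, 50)
        assert tuple(probes[-1]) == (1000, 1001)

    @pytest.mark.parametrize("length,width", [(0, 50), (1000, 0), (-5, 50)])
    def test_nonpositive_arguments_rejected(self, length, width):
        with pytest.raises(ValueError):
            tile_probes(length, width)


class TestCounting:
    def test_any_overlap_rule(self):
        probes = tile_probes(1000, 50)
        counts = count_reads(probes, [AlignedRead("chr", 0, 100)])
        assert counts[0] == 1 and counts[1] == 1 and counts[2:].sum() == 0
        counts = count_reads(probes, [AlignedRead("chr", 10, 40)])
        assert counts[0] == 1 and counts[1:].sum() == 0
        # a single-base overlap on either side still counts
        counts = count_reads(probes, [AlignedRead("chr", 49, 51)])
        assert counts[0] == 1 and counts[1] == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        probes = tile_probes(10_000, 50)
        reads = make_reads(rng, 1000, 10_000)
        assert np.array_equal(count_reads(probes, reads),
                              brute_force_counts(probes, reads))

    def test_non_unique_reads_never_counted(self):
        probes = tile_probes(1000, 50)
        reads = [AlignedRead("chr", 0, 100, unique=False)]
        assert count_reads(probes, reads).sum() == 0

    def test_out_of_bounds_read_is_hard_error(self):
        probes = tile_probes(1000, 50)
        with pytest.raises(ValueError, match="outside genome"):
            count_reads(probes, [AlignedRead("chr", 990, 1010)])

    @given(st.integers(0, 2**31 - 1))
    def test_read_order_never_changes_counts(self, seed):
        rng = np.random.default_rng(seed)
        probes = tile_probes(5_000, 50)
        reads = make_reads(rng, 200, 5_000)
        base = count_reads(probes, reads)
        perm = [reads[i] for i in rng.permutation(len(reads))]
        assert np.array_equal(count_reads(probes, perm), base)

    def test_duplicating_reads_doubles_counts_keeps_percent(self):
        rng = np.random.default_rng(3)
        probes = tile_probes(5_000, 50)
        reads = make_reads(rng, 300, 5_000)
        counts = count_reads(probes, reads)
        doubled = count_reads(probes, reads + reads)
        assert np.array_equal(doubled, 2 * counts)
        assert np.allclose(
            percent_normalize(counts, 300), percent_normalize(doubled, 600)
        )


class TestPercent:
    def test_simple_fractions(self):
        assert percent_normalize(np.array([2, 8]), 10).tolist() == [20.0, 80.0]

    def test_contained_reads_conserve_100_percent(self):
        # reads that never span a probe boundary contribute exactly once
        probes = tile_probes(1000, 50)
        reads = [AlignedRead("chr", i * 50 + 5, i * 50 + 45) for i in range(10)]
        counts = count_reads(probes, reads)
        assert percent_normalize(counts, len(reads)).sum() == pytest.approx(100.0)

    def test_boundary_spanning_reads_exceed_100_percent(self):
        probes = tile_probes(1000, 50)
        reads = [AlignedRead("chr", 40, 140) for _ in range(5)]
        counts = count_reads(probes, reads)
        assert percent_normalize(counts, 5).sum() > 100.0

    def test_zero_total_warns_and_zeroes(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = percent_normalize(np.array([0, 0]), 0)
        assert out.tolist() == [0.0, 0.0]
        assert any("total" in rec.message for rec in caplog.records)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            percent_normalize(np.array([-1, 2]), 10)
        with pytest.raises(ValueError):
            percent_normalize(np.array([1, 2]), -10)


class TestQuantify:
    def test_split_fragment_halves_count_once_in_total(self):
        genome = GenomeModel(name="chr", length=1000, circular=True)
        reads = [
            AlignedRead("chr", 950, 1000, name="f1"),
            AlignedRead("chr", 0, 30, name="f1"),
            AlignedRead("chr", 100, 200, name="f2"),
        ]
        assert total_unique_reads(reads) == 2
        track = quantify(genome, reads)
        assert track.total_unique_reads == 2
        assert track.counts[0] == 1 and track.counts[-1] == 1

    def test_track_invariants(self):
        genome = GenomeModel(name="chr", length=1001)
        reads = [AlignedRead("chr", 0, 100, name="a")]
        track = quantify(genome, reads)
        assert track.n_probes == 21
        assert np.all(track.percent >= 0)
        assert track.percent[0] == pytest.approx(100.0)
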