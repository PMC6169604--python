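"""Synthetic-data generator: determinism, conservation, planted signal."""
import numpy as np
import pytest
from scipy import stats

from chipcomp.io_formats import write_gff3
from chipcomp.occupancy import quantify
from chipcomp.synthetic import (
    EnrichmentSpec,
    SimulationConfig,
    demo_scenario,
    linear_intervals,
    make_genome,
    simulate_reads,
    truth_table,
)


def config_with(**kw):
    defaults = dict(genome_length=200_000, n_genes=0, n_reads_per_condition=10_000,
                    seed=1)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestMakeGenome:
    def test_zero_genes(self):
        genome = make_genome(config_with(n_genes=0))
        assert genome.genes == [] and genome.length == 200_000

    def test_deterministic_gff3_bytes(self, tmp_path):
        config = config_with(n_genes=50)
        paths = []
        for i in range(2):
            genome = make_genome(config)
            path = tmp_path / f"g{i}.gff3"
            write_gff3(genome, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_genes_on_both_strands_and_non_overlapping(self):
        genome = make_genome(config_with(n_genes=50))
        strands = {g.strand for g in genome.genes}
        assert strands == {"+", "-"}
        for a, b in zip(genome.genes, genome.genes[1:]):
            assert a.end <= b.start

    def test_infeasible_placement_is_hard_error(self):
        with pytest.raises(ValueError):
            make_genome(config_with(genome_length=5_000, n_genes=50))


class TestSimulateReads:
    def test_conservation_and_determinism(self):
        config = config_with(n_genes=10, n_reads_per_condition=5_000)
        genome = make_genome(config)
        reads1 = simulate_reads(genome, config, "wt")
        reads2 = simulate_reads(genome, config, "wt")
        assert reads1 == reads2
        assert len({r.name for r in reads1}) == 5_000  # split halves share names

    def test_zero_reads_is_empty_not_error(self):
        config = config_with(n_reads_per_condition=0)
        assert simulate_reads(make_genome(config), config, "wt") == []

    def test_missing_condition_in_fold_map_rejected(self):
        spec = EnrichmentSpec("x", 1_000, 500, {"wt": 2.0})
        config = config_with(enrichments=(spec,))
        with pytest.raises(ValueError, match="mutant"):
            simulate_reads(make_genome(config), config, "mutant")

    def test_fragment_lengths_match_shear_target(self):
        config = config_with(n_reads_per_condition=2_000)
        reads = simulate_reads(make_genome(config), config, "wt")
        by_name = {}
        for r in reads:
            by_name.setdefault(r.name, 0)
            by_name[r.name] += r.end - r.start
        lengths = np.array(list(by_name.values()))
        assert lengths.min() >= 300 and lengths.max() <= 500

    def test_background_is_uniform_chisquare_on_pooled_bins(self):
        """Fragment midpoints pooled into 2 kb bins are multinomial-uniform
        under no enrichment (probe-level overlap counts are correlated by the
        fragment span, so midpoints are the valid unit here)."""
        config = config_with(n_reads_per_condition=50_000)
        genome = make_genome(config)
        reads = simulate_reads(genome, config, "wt")
        firsts = {}
        for r in reads:  # reconstruct one midpoint per fragment
            firsts.setdefault(r.name, []).append((r.start, r.end))
        mids = []
        for parts in firsts.values():
            if len(parts) == 1:
                s, e = parts[0]
                mids.append((s + e) // 2)
            else:  # wrapped fragment: midpoint of the unwrapped interval
                (s1, e1), (s2, e2) = sorted(parts, key=lambda p: -p[0])
                mids.append((s1 + (e1 - s1 + e2 - s2) // 2) % genome.length)
        counts, _ = np.histogram(mids, bins=100, range=(0, genome.length))
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_planted_fold_recovers_expected_enrichment_ratio(self):
        spec = EnrichmentSpec("locus", 100_000, 500, {"wt": 10.0})
        config = config_with(n_reads_per_condition=200_000, enrichments=(spec,),
                             conditions=("wt",))
        genome = make_genome(config)
        track = quantify(genome, simulate_reads(genome, config, "wt"))
        probes = track.probes
        centers = (probes[:, 0] + probes[:, 1] - 1) // 2
        inside = (centers >= 99_500) & (centers < 100_500)
        # exclude the fragment-length spill zone around the window
        near = (centers >= 99_500 - 600) & (centers < 100_500 + 600)
        ratio = track.counts[inside].mean() / track.counts[~near].mean()
        assert 7.0 <= ratio <= 13.0

    def test_equal_folds_are_exchangeable_between_conditions(self):
        spec = EnrichmentSpec("locus", 50_000, 500, {"A": 1.0, "B": 1.0})
        config = config_with(n_reads_per_condition=20_000, enrichments=(spec,),
                             conditions=("A", "B"))
        genome = make_genome(config)
        ta = quantify(genome, simulate_reads(genome, config, "A"))
        tb = quantify(genome, simulate_reads(genome, config, "B"))
        p = stats.ks_2samp(ta.counts, tb.counts).pvalue
        assert p > 0.001


class TestTruthTable:
    def test_one_row_per_locus_condition_pair(self):
        specs = tuple(
            EnrichmentSpec(f"s{i}", 10_000 * (i + 1), 500, {"A": 2.0, "B": 1.0})
            for i in range(3)
        )
        config = config_with(enrichments=specs, conditions=("A", "B"))
        table = truth_table(config)
        assert len(table) == 6
        assert set(table["condition"]) == {"A", "B"}

    def test_background_flag_and_purity(self):
        specs = (
            EnrichmentSpec("flat", 10_000, 500, {"A": 1.0, "B": 1.0}),
            EnrichmentSpec("hot", 20_000, 500, {"A": 5.0, "B": 1.0}),
        )
        config = config_with(enrichments=specs, conditions=("A", "B"))
        t1, t2 = truth_table(config), truth_table(config)
        assert t1.equals(t2)  # pure function of config
        assert t1.loc[t1.locus_id == "flat", "background"].all()
        assert not t1.loc[t1.locus_id == "hot", "background"].any()


class TestLinearIntervals:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (100, 200, [(100, 200)]),
            (-50, 50, [(950, 1000), (0, 50)]),
            (950, 1050, [(950, 1000), (0, 50)]),
            (0, 1000, [(0, 1000)]),
            (200, 200, []),
        ],
    )
    def test_wrapping(self, lo, hi, expected):
        assert linear_intervals(lo, hi, 1000, circular=True) == expected

    def test_linear_clip(self):
        assert linear_intervals(-50, 50, 1000, circular=False) == [(0, 50)]


class TestDemoScenario:
    def test_three_loci_one_differential(self):
        config, genome = demo_scenario(seed=0, genome_length=60_000, n_genes=15,
                                       n_reads_per_condition=1_000)
        assert len(config.enrichments) == 3
        folds = [
            (s.fold_by_condition["wt"], s.fold_by_condition["mutant"])
            for s in config.enrichments
        ]
        assert folds.count((10.0, 10.0)) == 2
        assert folds.count((1.0, 10.0)) == 1
        assert genome.n_genes == 15
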