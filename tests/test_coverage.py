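"""Coverage ratios, element capture, CpG strata, promoter and metagene profiles."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_covered_bases
from hmedip.coverage import (
    classify_cpg_density,
    chromosome_coverage_table,
    coverage_ratio,
    cpg_density_strata,
    element_capture,
    metagene_profile,
    promoter_rpkm_summary,
)
from hmedip.errors import ConfigError, DataError
from hmedip.simulate import GeneModel
from hmedip.windows import (
    CoveredWindowSet,
    RpkmTrack,
    WindowCountTrack,
    covered_windows,
    make_windows,
)


def _covered(grid, covered_windows_idx):
    mask = np.zeros(grid.total_windows, dtype=bool)
    mask[list(covered_windows_idx)] = True
    return CoveredWindowSet(grid, mask)


def _targets(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestCoverageRatio:
    def test_target_inside_covered_windows(self):
        grid = make_windows({"c": 1000})
        r = coverage_ratio(_covered(grid, range(10)), _targets([("c", 120, 480)]))
        assert r.ratio == 1.0

    def test_target_disjoint_from_covered(self):
        grid = make_windows({"c": 1000})
        r = coverage_ratio(_covered(grid, [9]), _targets([("c", 0, 500)]))
        assert r.ratio == 0.0

    def test_partial_overlap_hand_computed(self):
        # target [50, 250) with only window [100, 200) covered -> 100/200
        grid = make_windows({"c": 1000})
        r = coverage_ratio(_covered(grid, [1]), _targets([("c", 50, 250)]))
        assert r.covered_bases == 100 and r.total_bases == 200
        assert r.ratio == 0.5

    def test_overlapping_targets_counted_once(self):
        grid = make_windows({"c": 1000})
        r = coverage_ratio(
            _covered(grid, range(10)), _targets([("c", 0, 300), ("c", 200, 400)])
        )
        assert r.total_bases == 400

    def test_empty_target_rejected(self):
        grid = make_windows({"c": 1000})
        with pytest.raises(DataError):
            coverage_ratio(_covered(grid, [0]), _targets([]))

    def test_agrees_with_base_resolution_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(1000):
            chrom_len = int(rng.integers(80, 400))
            width = int(rng.integers(10, 120))
            grid = make_windows({"c": chrom_len}, width)
            mask = rng.random(grid.total_windows) < 0.4
            n_t = int(rng.integers(1, 6))
            starts = rng.integers(0, chrom_len - 1, size=n_t)
            ends = np.minimum(starts + rng.integers(1, 150, size=n_t), chrom_len)
            targets = list(zip(starts.tolist(), ends.tolist()))
            expected = brute_force_covered_bases(chrom_len, width, mask, targets)
            got = coverage_ratio(
                CoveredWindowSet(grid, mask),
                _targets([("c", s, e) for s, e in targets]),
            )
            assert got.covered_bases == expected

    def test_per_chromosome_ratios_aggregate_to_genome(self):
        rng = np.random.default_rng(2)
        grid = make_windows({"a": 1050, "b": 730}, 100)
        mask = rng.random(grid.total_windows) < 0.5
        table = chromosome_coverage_table(CoveredWindowSet(grid, mask))
        chroms = table[table["target"] != "genome"]
        genome = table[table["target"] == "genome"].iloc[0]
        weighted = (
            chroms["ratio"] * chroms["total_bases"]
        ).sum() / chroms["total_bases"].sum()
        assert genome["ratio"] == pytest.approx(weighted)


class TestElementCapture:
    def test_no_covered_windows(self):
        grid = make_windows({"c": 1000})
        n, _ = element_capture(_covered(grid, []), _targets([("c", 0, 100)]))
        assert n == 0

    def test_counting_fraction(self):
        grid = make_windows({"c": 1000})
        elements = _targets([("c", 0, 50), ("c", 150, 160), ("c", 300, 420), ("c", 900, 950)])
        n, frac = element_capture(_covered(grid, [0, 1, 3]), elements)
        assert (n, frac) == (3, 0.75)

    def test_single_base_overlap_captures(self):
        grid = make_windows({"c": 1000})
        # element [199, 300) touches covered window [100, 200) by one base
        n, _ = element_capture(_covered(grid, [1]), _targets([("c", 199, 300)]))
        assert n == 1

    def test_empty_elements_not_applicable(self):
        grid = make_windows({"c": 1000})
        n, frac = element_capture(_covered(grid, [0]), _targets([]))
        assert n == 0 and np.isnan(frac)

    def test_monotone_in_covered_windows(self):
        rng = np.random.default_rng(4)
        grid = make_windows({"c": 2000})
        starts = rng.integers(0, 1900, size=15)
        elements = _targets([("c", int(s), int(s) + 80) for s in starts])
        prev = -1
        for k in range(0, 21, 5):
            n, _ = element_capture(_covered(grid, range(k)), elements)
            assert n >= prev
            prev = n


class TestCpgStrata:
    @pytest.mark.parametrize("n_cpg,expected", [(0, "low"), (1, "moderate"),
                                                (5, "moderate"), (6, "high")])
    def test_class_boundaries(self, n_cpg, expected):
        grid = make_windows({"c": 100})
        pos = {"c": np.arange(n_cpg, dtype=np.int64) * 10}
        assert classify_cpg_density(grid, pos)[0] == expected

    def test_classes_partition_and_density(self):
        grid = make_windows({"c": 1000})
        pos = {"c": np.array([0, 10, 210, 220, 230, 240, 250, 260])}
        counts = np.array([4, 0, 8, 0, 0, 0, 0, 0, 0, 0])
        track = WindowCountTrack(grid, counts, library_total=12)
        rpkm = RpkmTrack(grid, counts.astype(float), 12)
        strata = cpg_density_strata(grid, pos, covered_windows(track), rpkm)
        assert strata["n_windows"].sum() == 10
        by = strata.set_index("cpg_class")
        assert by.loc["moderate", "n_windows"] == 1  # window 0: 2 CpGs
        assert by.loc["high", "n_windows"] == 1  # window 2: 6 CpGs
        assert by.loc["moderate", "mean_rpkm"] == pytest.approx(4.0)
        assert by.loc["high", "mean_rpkm"] == pytest.approx(8.0)
        assert np.isnan(by.loc["low", "mean_rpkm"])  # no covered low window


class TestPromoterSummary:
    def _promoters(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end", "strand"]
        )

    def test_uniform_rpkm_gives_that_mean(self):
        grid = make_windows({"c": 10_000})
        rpkm = RpkmTrack(grid, np.full(grid.total_windows, 7.5), 10**6)
        covered = CoveredWindowSet(grid, np.ones(grid.total_windows, dtype=bool))
        promoters = self._promoters([("g1", "c", 1000, 3000, "+"), ("g2", "c", 5000, 7000, "+")])
        n, frac, mean = promoter_rpkm_summary(rpkm, covered, promoters)
        assert (n, frac) == (2, 1.0)
        assert mean == pytest.approx(7.5)

    def test_zero_coverage_gives_nan_mean(self):
        grid = make_windows({"c": 10_000})
        rpkm = RpkmTrack(grid, np.zeros(grid.total_windows), 10**6)
        covered = CoveredWindowSet(grid, np.zeros(grid.total_windows, dtype=bool))
        n, frac, mean = promoter_rpkm_summary(
            rpkm, covered, self._promoters([("g1", "c", 1000, 3000, "+")])
        )
        assert n == 0 and frac == 0 and np.isnan(mean)


class TestMetagene:
    def _gene(self, strand, tss, chrom_len=100_000):
        if strand == "+":
            start, end = tss, tss + 3000
        else:
            start, end = tss - 2999, tss + 1
        return GeneModel("g1", "c", strand, start, end, parts=[])

    def _rpkm(self, values, chrom_len=100_000):
        grid = make_windows({"c": chrom_len})
        return RpkmTrack(grid, values, 10**6)

    def test_six_bins_with_default_window(self):
        vals = np.zeros(1000)
        profile = metagene_profile(self._rpkm(vals), [self._gene("+", 50_000)])
        assert len(profile) == 6
        assert profile["offset_start"].tolist() == [-2500, -2000, -1500, -1000, -500, 0]

    def test_uniform_signal_is_flat(self):
        vals = np.full(1000, 3.0)
        profile = metagene_profile(self._rpkm(vals), [self._gene("+", 50_000)])
        assert np.allclose(profile["mean_rpkm"], 3.0)

    def test_minus_strand_mirrors_plus(self):
        # one hot window just downstream of the TSS shows up in bin 6 on
        # both strands; on the minus strand "downstream" is the lower side
        tss = 50_000
        vals_plus = np.zeros(1000)
        vals_plus[(tss + 100) // 100] = 9.0  # [50100, 50200), offsets +100..+200
        plus = metagene_profile(self._rpkm(vals_plus), [self._gene("+", tss)])
        vals_minus = np.zeros(1000)
        vals_minus[(tss - 200) // 100] = 9.0  # [49800, 49900), offsets +101..+200
        minus = metagene_profile(self._rpkm(vals_minus), [self._gene("-", tss)])
        for prof in (plus, minus):
            hot = prof[prof["mean_rpkm"] > 0]["bin"].tolist()
            assert hot == [6]
        # hand-check magnitude: 100 hot bases of 500 in the bin -> 9 * 100/500
        assert plus[plus["bin"] == 6]["mean_rpkm"].iloc[0] == pytest.approx(9 * 100 / 500)
        assert minus[minus["bin"] == 6]["mean_rpkm"].iloc[0] == pytest.approx(9 * 100 / 500)

    def test_out_of_bounds_bins_are_excluded(self):
        # TSS so close to the chromosome start that upstream bins are empty
        vals = np.full(1000, 2.0)
        profile = metagene_profile(self._rpkm(vals), [self._gene("+", 400, 100_000)])
        assert profile[profile["bin"] == 1]["n_genes"].iloc[0] == 0
        assert np.isnan(profile[profile["bin"] == 1]["mean_rpkm"].iloc[0])
        assert profile[profile["bin"] == 6]["mean_rpkm"].iloc[0] == pytest.approx(2.0)

    def test_window_must_divide_into_bins(self):
        with pytest.raises(ConfigError):
            metagene_profile(
                self._rpkm(np.zeros(1000)), [self._gene("+", 50_000)],
                window=(-2500, 500), bin_size=400,
            )
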