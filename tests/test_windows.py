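"""Window grid, read counting, RPKM, covered regions and library QC."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_window_counts
from hmedip.errors import ConfigError, DataError
from hmedip.windows import (
    WindowCountTrack,
    count_reads,
    covered_windows,
    cpg_enrichment_score,
    make_windows,
    saturation_analysis,
    to_rpkm,
)


def _frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,width,expected_n,last_len",
        [(1000, 100, 10, 100), (1050, 100, 11, 50), (99, 100, 1, 99)],
    )
    def test_tiling(self, length, width, expected_n, last_len):
        grid = make_windows({"c": length}, width)
        assert grid.total_windows == expected_n
        assert grid.window_lengths("c")[-1] == last_len
        starts, ends = grid.window_bounds("c")
        assert starts[0] == 0 and ends[-1] == length

    def test_default_width_is_100bp(self):
        assert make_windows({"c": 1000}).width == 100

    def test_invalid_parameters(self):
        with pytest.raises(ConfigError):
            make_windows({"c": 1000}, width=0)
        with pytest.raises(ConfigError):
            make_windows({"c": -5}, width=100)


class TestCountReads:
    def test_no_reads_gives_zero_track(self):
        grid = make_windows({"c": 1000})
        track = count_reads(grid, _frame([]))
        assert track.library_total == 0
        assert track.counts.sum() == 0

    def test_boundary_spanning_read_counts_in_both_windows(self):
        grid = make_windows({"c": 1000})
        track = count_reads(grid, _frame([("c", 95, 146)]))
        assert list(track.counts[:3]) == [1, 1, 0]

    def test_half_open_boundaries(self):
        # a read exactly [100, 200) touches only the second window
        grid = make_windows({"c": 1000})
        track = count_reads(grid, _frame([("c", 100, 200)]))
        assert list(track.counts[:3]) == [0, 1, 0]

    def test_unknown_chromosome_named_in_error(self):
        grid = make_windows({"c": 1000})
        with pytest.raises(DataError, match="chrM"):
            count_reads(grid, _frame([("chrM", 0, 50)]))

    def test_out_of_bounds_read_rejected(self):
        grid = make_windows({"c": 1000})
        with pytest.raises(DataError):
            count_reads(grid, _frame([("c", 990, 1041)]))

    def test_mapq_filter_drops_low_quality(self):
        grid = make_windows({"c": 1000})
        df = pd.DataFrame(
            {"chrom": "c", "start": [0, 10], "end": [50, 60], "name": ".",
             "score": [10, 30]}
        )
        track = count_reads(grid, df, min_mapq=20)
        assert track.library_total == 1

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            chrom_len = int(rng.integers(50, 500))
            width = int(rng.integers(10, 120))
            grid = make_windows({"c": chrom_len}, width)
            n_reads = int(rng.integers(0, 30))
            starts = rng.integers(0, max(1, chrom_len - 1), size=n_reads)
            lengths = rng.integers(1, 60, size=n_reads)
            ends = np.minimum(starts + lengths, chrom_len)
            reads = list(zip(starts.tolist(), ends.tolist()))
            expected = brute_force_window_counts(chrom_len, width, reads)
            got = count_reads(
                grid, _frame([("c", s, e) for s, e in reads])
            ).counts
            assert np.array_equal(got, expected)


class TestRpkm:
    def test_formula(self):
        grid = make_windows({"c": 1000})
        track = WindowCountTrack(grid, [10] + [0] * 9, library_total=1_000_000)
        rpkm = to_rpkm(track)
        assert rpkm.values[0] == pytest.approx(100.0)
        assert (rpkm.values[1:] == 0).all()

    def test_formula_other_library_size(self):
        grid = make_windows({"c": 100})
        track = WindowCountTrack(grid, [1], library_total=2_000_000)
        assert to_rpkm(track).values[0] == pytest.approx(5.0)

    def test_truncated_window_uses_actual_length(self):
        grid = make_windows({"c": 150})
        track = WindowCountTrack(grid, [1, 1], library_total=1_000_000)
        rpkm = to_rpkm(track)
        assert rpkm.values[1] == pytest.approx(2 * rpkm.values[0])

    def test_empty_library_is_an_error(self):
        grid = make_windows({"c": 1000})
        track = WindowCountTrack(grid, [0] * 10, library_total=0)
        with pytest.raises(DataError):
            to_rpkm(track)

    def test_mass_conservation(self):
        # sum over windows of RPKM * kb * millions recovers the raw count sum
        rng = np.random.default_rng(0)
        grid = make_windows({"a": 1050, "b": 430}, 100)
        counts = rng.integers(0, 20, size=grid.total_windows)
        track = WindowCountTrack(grid, counts, library_total=int(counts.sum()))
        rpkm = to_rpkm(track)
        back = (
            rpkm.values
            * (grid.all_window_lengths() / 1000)
            * (track.library_total / 1e6)
        ).sum()
        assert back == pytest.approx(counts.sum())


class TestCoveredWindows:
    def test_zero_track_empty(self):
        grid = make_windows({"c": 1000})
        cov = covered_windows(WindowCountTrack(grid, [0] * 10, 0))
        assert cov.covered_count == 0 and cov.fraction == 0

    def test_single_read_covers(self):
        grid = make_windows({"c": 1000})
        cov = covered_windows(count_reads(grid, _frame([("c", 0, 1)])))
        assert cov.covered_count == 1

    def test_fraction_counting(self):
        grid = make_windows({"c": 1000})
        counts = [1, 2, 0, 3, 1, 0, 0, 1, 1, 1]
        cov = covered_windows(WindowCountTrack(grid, counts, 10))
        assert cov.fraction == pytest.approx(0.7)

    def test_monotone_under_added_reads(self):
        rng = np.random.default_rng(3)
        grid = make_windows({"c": 2000})
        reads = [("c", int(s), int(s) + 51) for s in rng.integers(0, 1949, size=60)]
        prev = -1
        for n in (0, 10, 30, 60):
            cov = covered_windows(count_reads(grid, _frame(reads[:n])))
            assert cov.covered_count >= prev
            prev = cov.covered_count


class TestSaturation:
    def test_identical_reads_correlate_perfectly(self):
        # every read is the same interval, so any split gives proportional tracks
        grid = make_windows({"c": 1000})
        reads = _frame([("c", 200, 251)] * 40)
        res = saturation_analysis(reads, grid, steps=5, seed=0)
        assert len(res.fractions) == 5
        assert np.allclose(res.truncated, 1.0)
        assert np.allclose(res.estimated, 1.0)

    def test_requires_two_reads(self):
        grid = make_windows({"c": 1000})
        with pytest.raises(DataError):
            saturation_analysis(_frame([("c", 0, 51)]), grid)

    def test_curve_monotone_in_expectation(self):
        # heterogeneous window intensities (an enrichment landscape) make the
        # two halves genuinely correlated; the mean curve over seeds must rise
        rng = np.random.default_rng(5)
        grid = make_windows({"c": 50_000})
        weights = rng.gamma(0.5, 2.0, size=500)
        win = rng.choice(500, size=4000, p=weights / weights.sum())
        starts = win * 100 + rng.integers(0, 49, size=4000)
        reads = _frame([("c", int(s), int(s) + 51) for s in starts])
        curves = [
            saturation_analysis(reads, grid, steps=5, seed=seed).truncated
            for seed in range(20)
        ]
        mean = np.mean(curves, axis=0)
        assert (np.diff(mean) > -0.01).all()
        assert mean[-1] > mean[0]


class TestCpgEnrichment:
    def test_full_genome_tiling_scores_one(self):
        sizes = {"c": 1000}
        cpgs = {"c": np.array([5, 105, 250, 700])}
        reads = _frame([("c", 0, 500), ("c", 500, 1000)])
        assert cpg_enrichment_score(reads, cpgs, sizes) == pytest.approx(1.0)

    def test_reads_in_cpg_dense_region_score_two(self):
        # density 2/100bp inside [0, 500), 1/100bp overall
        sizes = {"c": 1000}
        dense = np.arange(0, 500, 50)  # 10 CpGs in 500 bp
        cpgs = {"c": dense}  # genome density 10/1000 = 1 per 100 bp
        reads = _frame([("c", 0, 500)])
        assert cpg_enrichment_score(reads, cpgs, sizes) == pytest.approx(2.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            cpg_enrichment_score(_frame([]), {"c": np.array([1])}, {"c": 100})
        with pytest.raises(DataError):
            cpg_enrichment_score(_frame([("c", 0, 50)]), {}, {"c": 100})
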