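"""Toy-genome construction, planted signal and the NB read simulator."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from hmedip.coverage import classify_cpg_density
from hmedip.errors import ConfigError, DataError
from hmedip.simulate import (
    GENE_PART_ORDER,
    PlantedSignal,
    SimulationConfig,
    build_toy_genome,
    load_fixtures,
    plant_dhmr_signals,
    simulate_reads,
    write_fixtures,
)
from hmedip.windows import count_reads, make_windows


def small_config(**kw) -> SimulationConfig:
    defaults = dict(
        seed=5,
        chrom_sizes={"chr1": 100_000, "chr2": 100_000},
        n_genes=20,
        n_cgis=8,
        n_hyper=10,
        n_hypo=4,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_fold_change_must_exceed_one(self):
        with pytest.raises(ConfigError):
            small_config(fold_change=1.0).validate()

    def test_too_many_planted_windows(self):
        with pytest.raises(ConfigError):
            small_config(n_hyper=10**6).validate()

    def test_negative_depth(self):
        with pytest.raises(ConfigError):
            small_config(depth_per_window=-1).validate()

    def test_genes_must_fit_chromosome(self):
        cfg = small_config(
            chrom_sizes={"chr1": 8000, "chr2": 8000}, n_genes=4, n_cgis=0
        )
        with pytest.raises(ConfigError, match="gene"):
            build_toy_genome(cfg)


class TestToyGenome:
    def test_gene_models_well_formed(self, toy_genome, desk_config):
        assert len(toy_genome.gene_models) == desk_config.n_genes
        for g in toy_genome.gene_models:
            assert 0 <= g.start < g.end <= toy_genome.chrom_sizes[g.chrom]
            # parts tile the transcribed unit without gaps or overlaps
            parts = sorted(g.parts, key=lambda p: p[1])
            assert parts[0][1] == g.start and parts[-1][2] == g.end
            for (_, _, e1), (_, s2, _) in zip(parts, parts[1:]):
                assert e1 == s2
            labels = [p[0] for p in sorted(g.parts, key=lambda p: p[1])]
            expected = (
                list(GENE_PART_ORDER)
                if g.strand == "+"
                else list(reversed(GENE_PART_ORDER))
            )
            assert labels == expected

    def test_cpg_positions_strictly_increasing(self, toy_genome):
        for chrom, pos in toy_genome.cpg_positions.items():
            assert (np.diff(pos) > 0).all()
            assert pos.min() >= 0 and pos.max() < toy_genome.chrom_sizes[chrom]

    def test_cgis_create_high_density_windows(self, toy_genome, desk_config):
        grid = make_windows(toy_genome.chrom_sizes, 100)
        classes = classify_cpg_density(grid, toy_genome.cpg_positions)
        assert (classes == "high").sum() >= desk_config.n_cgis

    def test_bivalent_is_forced_intersection(self, toy_genome):
        assert toy_genome.bivalent_ids == (
            toy_genome.h3k4me3_ids & toy_genome.h3k27me3_ids
        )
        assert len(toy_genome.bivalent_ids) > 0
        assert toy_genome.highly_expressed_ids <= toy_genome.expressed_ids
        assert not (toy_genome.repressed_ids & toy_genome.expressed_ids)

    def test_deterministic_for_fixed_seed(self):
        cfg = small_config()
        assert build_toy_genome(cfg) == build_toy_genome(small_config())


class TestPlantedSignal:
    def test_empty_request(self, toy_genome):
        cfg = small_config(n_hyper=0, n_hypo=0)
        sig = plant_dhmr_signals(build_toy_genome(cfg), cfg)
        assert len(sig) == 0

    def test_counts_disjoint_and_grid_aligned(self):
        cfg = small_config(n_hyper=50, n_hypo=0)
        genome = build_toy_genome(cfg)
        sig = plant_dhmr_signals(genome, cfg)
        recs = sig.records
        assert (recs["direction"] == "hyper").sum() == 50
        assert (recs["start"] % 100 == 0).all()
        assert not recs.duplicated(["chrom", "start"]).any()

    def test_insufficient_windows_reports_sizes(self):
        cfg = small_config(chrom_sizes={"chr1": 100_000}, n_genes=5, n_cgis=2)
        genome = build_toy_genome(cfg)
        cfg.n_hyper = 10_000
        with pytest.raises((ConfigError, DataError), match="10"):
            plant_dhmr_signals(genome, cfg)


class TestSimulateReads:
    def test_zero_depth_gives_no_reads(self):
        cfg = small_config(depth_per_window=0)
        genome = build_toy_genome(cfg)
        sig = plant_dhmr_signals(genome, cfg)
        assert len(simulate_reads(genome, sig, cfg, "control")) == 0

    def test_reads_are_51bp_and_inside_chromosomes(self, read_pair, toy_genome):
        for df in read_pair.values():
            assert ((df["end"] - df["start"]) == 51).all()
            for chrom, group in df.groupby("chrom"):
                assert group["start"].min() >= 0
                assert group["end"].max() <= toy_genome.chrom_sizes[chrom]

    def test_poisson_mean_matches_depth(self):
        # phi=0, depth 2: mean background window count within 3 SE of 2
        cfg = SimulationConfig(
            seed=9, depth_per_window=2.0, dispersion=0.0, n_hyper=0, n_hypo=0
        )
        genome = build_toy_genome(cfg)
        sig = plant_dhmr_signals(genome, cfg)
        reads = simulate_reads(genome, sig, cfg, "control")
        grid = cfg.grid()
        # use read start positions to recover the per-window draws exactly
        counts = np.zeros(grid.total_windows, dtype=int)
        for chrom, group in reads.groupby("chrom"):
            idx = group["start"].to_numpy() // 100
            counts[grid.offset(chrom) : grid.offset(chrom) + grid.n_windows(chrom)] += (
                np.bincount(idx, minlength=grid.n_windows(chrom))
            )
        se = np.sqrt(2.0 / grid.total_windows)
        assert abs(counts.mean() - 2.0) < 3 * se

    def test_nb_variance_relation(self):
        # var ~ mu + phi mu^2 across 10,000 iid background windows
        phi, depth = 0.3, 10.0
        cfg = SimulationConfig(seed=13, depth_per_window=depth, dispersion=phi,
                               n_hyper=0, n_hypo=0)
        genome = build_toy_genome(cfg)
        sig = plant_dhmr_signals(genome, cfg)
        reads = simulate_reads(genome, sig, cfg, "control")
        grid = cfg.grid()
        counts = np.zeros(grid.total_windows, dtype=int)
        for chrom, group in reads.groupby("chrom"):
            idx = group["start"].to_numpy() // 100
            counts[grid.offset(chrom) : grid.offset(chrom) + grid.n_windows(chrom)] += (
                np.bincount(idx, minlength=grid.n_windows(chrom))
            )
        expected_var = depth + phi * depth**2
        assert counts.var() == pytest.approx(expected_var, rel=0.15)

    def test_planted_fold_recovered_empirically(self):
        # many planted hyper windows: mean exposed/control count ratio -> fold
        cfg = SimulationConfig(
            seed=17, depth_per_window=20.0, dispersion=0.0, n_hyper=200, n_hypo=0,
            fold_change=4.0,
        )
        genome = build_toy_genome(cfg)
        sig = plant_dhmr_signals(genome, cfg)
        grid = cfg.grid()
        # recover the generator's per-window draws via read start positions
        # (overlap counting would mix in neighbouring-window spillover)
        draws = {}
        for cond in ("control", "exposed"):
            reads = simulate_reads(genome, sig, cfg, cond)
            counts = np.zeros(grid.total_windows, dtype=int)
            for chrom, group in reads.groupby("chrom"):
                idx = group["start"].to_numpy() // 100
                o = grid.offset(chrom)
                counts[o : o + grid.n_windows(chrom)] += np.bincount(
                    idx, minlength=grid.n_windows(chrom)
                )
            draws[cond] = counts
        planted_idx = np.array(
            [grid.offset(r.chrom) + r.start // 100 for r in sig.records.itertuples()]
        )
        ratio = draws["exposed"][planted_idx].mean() / draws["control"][planted_idx].mean()
        # 200 windows at depth 20: MC standard error of the ratio ~ 3%
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_library_size_ratio_approximate(self, read_pair, desk_config):
        ratio = len(read_pair["exposed"]) / len(read_pair["control"])
        assert ratio == pytest.approx(desk_config.library_size_ratio, rel=0.05)

    def test_unknown_condition_rejected(self, toy_genome, planted, desk_config):
        with pytest.raises(ConfigError):
            simulate_reads(toy_genome, planted, desk_config, "treated")


class TestFixtureBundle:
    def test_round_trip_reproduces_objects(self, fixture_bundle, toy_genome, planted, read_pair):
        genome2, signal2, reads2 = load_fixtures(fixture_bundle)
        assert genome2 == toy_genome
        assert signal2 == planted
        for cond in ("control", "exposed"):
            got = reads2[cond][["chrom", "start", "end"]].reset_index(drop=True)
            want = read_pair[cond][["chrom", "start", "end"]].reset_index(drop=True)
            pd.testing.assert_frame_equal(got, want)

    def test_truth_table_row_count(self, fixture_bundle, desk_config):
        truth = pd.read_csv(fixture_bundle / "truth.tsv", sep="\t")
        assert len(truth) == desk_config.n_hyper + desk_config.n_hypo

    def test_bed_and_gff_coordinate_conventions(self, fixture_bundle, toy_genome):
        # GFF is 1-based closed: starts shift by +1 relative to the 0-based model
        g = toy_genome.gene_models[0]
        gff_lines = [
            l.split("\t")
            for l in (fixture_bundle / "genes.gff").read_text().splitlines()
            if not l.startswith("#")
        ]
        gene_line = next(
            l for l in gff_lines if l[2] == "gene" and f"ID={g.gene_id}" in l[8]
        )
        assert int(gene_line[3]) == g.start + 1
        assert int(gene_line[4]) == g.end
        # BED stays 0-based half-open
        cgi_bed = pd.read_csv(fixture_bundle / "cgis.bed", sep="\t", header=None)
        assert cgi_bed.iloc[0, 1] == toy_genome.cgis.iloc[0]["start"]

    def test_bundle_byte_identical_across_runs(self, tmp_path):
        cfg = small_config()
        for sub in ("a", "b"):
            genome = build_toy_genome(small_config())
            sig = plant_dhmr_signals(genome, small_config())
            reads = {
                c: simulate_reads(genome, sig, small_config(), c)
                for c in ("control", "exposed")
            }
            write_fixtures(genome, sig, reads, tmp_path / sub)
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files
        for name in files:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name
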