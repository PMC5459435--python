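"""End-to-end orchestration: reads -> QC -> profiles -> DhMRs -> annotation -> enrichment.

A :class:`PipelineConfig` names every input file and every tunable
parameter; :func:`run_pipeline` runs the full chain deterministically for
a given seed, writes tidy TSV outputs, and returns a :class:`RunReport`
whose internal-consistency checks (hyper + hypo = total DhMRs, gene-set
union arithmetic, CpG-class partition) either pass or fail the run loudly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import annotate, coverage, enrichment, io, windows
from .dhmr import ExactTestParams, call_dhmrs
from .errors import ConfigError, DataError

log = logging.getLogger("hmedip")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Input paths and parameters of a full pipeline run."""

    chrom_sizes: Path
    reads_control: Path
    reads_exposed: Path
    genes: Path
    cgis: Path
    repeats: Path
    cpg: Path
    geneset_files: dict[str, Path] = field(default_factory=dict)
    imprinted_file: Path | None = None
    truth: Path | None = None
    out_dir: Path = Path("hmedip_out")
    seed: int = 0
    window_width: int = 100
    dispersion: float = 0.1
    p_threshold: float = 0.005
    min_total_count: int = 1
    promoter_upstream: int = 2000
    tts_width: int = 1000
    metagene_window: tuple[int, int] = (-2500, 500)
    metagene_bin: int = 500
    saturation_steps: int = 10

    @classmethod
    def from_fixture_dir(
        cls, fixture_dir: str | Path, out_dir: str | Path, **overrides: Any
    ) -> "PipelineConfig":
        """Wire a config onto a fixture bundle written by ``write_fixtures``."""
        d = Path(fixture_dir)
        genesets = {
            p.stem.removeprefix("geneset_"): p
            for p in sorted(d.glob("geneset_*.txt"))
            if p.stem != "geneset_imprinted"
        }
        truth = d / "truth.tsv"
        return cls(
            chrom_sizes=d / "chrom.sizes",
            reads_control=d / "reads_control.bed",
            reads_exposed=d / "reads_exposed.bed",
            genes=d / "genes.gff",
            cgis=d / "cgis.bed",
            repeats=d / "repeats.bed",
            cpg=d / "cpg.bed",
            geneset_files=genesets,
            imprinted_file=(d / "geneset_imprinted.txt"),
            truth=truth if truth.exists() else None,
            out_dir=Path(out_dir),
            **overrides,
        )

    def validate(self) -> None:
        for name in ("chrom_sizes", "reads_control", "reads_exposed", "genes",
                     "cgis", "repeats", "cpg"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"missing input file for {name}: {p}")
        for name, p in self.geneset_files.items():
            if not Path(p).exists():
                raise ConfigError(f"missing gene-set file {name}: {p}")


@dataclass
class RunReport:
    """All result blocks of one run, with consistency guarantees."""

    qc: dict
    coverage: dict
    dhmr: dict
    annotation: dict
    enrichment: pd.DataFrame
    benchmark: dict | None = None

    def check_consistency(self) -> None:
        d = self.dhmr
        if d["hyper"] + d["hypo"] != d["total"]:
            raise DataError("DhMR arithmetic broken: hyper + hypo != total")
        a = self.annotation["gene_summary"]
        if a["hyper_genes"] + a["hypo_genes"] - a["both_directions"] != a["affected_genes"]:
            raise DataError("affected-gene set arithmetic broken")
        strata = self.coverage["cpg_strata"]
        for cond, group in strata.groupby("condition"):
            if group["n_windows"].sum() != self.coverage["total_windows"]:
                raise DataError(
                    f"CpG-density classes do not partition the windows ({cond})"
                )

    def summary_dict(self) -> dict:
        out = {
            "qc": self.qc,
            "dhmr": self.dhmr,
            "annotation": {
                "gene_summary": self.annotation["gene_summary"],
                "feature_distribution": self.annotation["feature_distribution"],
            },
        }
        if self.benchmark:
            out["benchmark"] = self.benchmark
        return out


def _condition_stats(
    name: str,
    reads: pd.DataFrame,
    grid: windows.WindowGrid,
    cpgs: Mapping[str, np.ndarray],
    genome_sizes: Mapping[str, int],
    cfg: PipelineConfig,
    rng_seed: int,
) -> dict:
    track = windows.count_reads(grid, reads)
    rpkm = windows.to_rpkm(track)
    covered = windows.covered_windows(track)
    sat = windows.saturation_analysis(reads, grid, steps=cfg.saturation_steps, seed=rng_seed)
    enr = windows.cpg_enrichment_score(reads, cpgs, genome_sizes)
    # fraction of CpG sites sequenced to >= 1x (inside read-covered bases)
    n_cpg = sum(len(v) for v in cpgs.values())
    covered_cpgs = 0
    for chrom in grid.chroms:
        pos = cpgs.get(chrom)
        if pos is None or not len(pos):
            continue
        mask = covered.chrom_mask(chrom)
        covered_cpgs += int(mask[pos // grid.width].sum())
    return {
        "name": name,
        "track": track,
        "rpkm": rpkm,
        "covered": covered,
        "saturation": sat,
        "cpg_enrichment": enr,
        "cpg_coverage_fraction": covered_cpgs / n_cpg if n_cpg else float("nan"),
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    chrom_sizes = io.read_chrom_sizes(config.chrom_sizes)
    genes = io.read_gene_models_gff(config.genes)
    cgis = io.read_bed(config.cgis, names=["chrom", "start", "end", "name"])
    repeats = io.read_bed(config.repeats, names=["chrom", "start", "end", "name"]).rename(
        columns={"name": "repeat_class"}
    )
    cpg_df = io.read_bed(config.cpg, names=["chrom", "start", "end"])
    cpgs = {
        chrom: np.sort(g["start"].to_numpy(dtype=np.int64))
        for chrom, g in cpg_df.groupby("chrom", sort=False)
    }
    reads = {
        "control": io.read_bed(config.reads_control),
        "exposed": io.read_bed(config.reads_exposed),
    }
    gene_sets = {
        name: io.read_gene_list(path) for name, path in config.geneset_files.items()
    }
    imprinted = (
        io.read_labeled_gene_list(config.imprinted_file)
        if config.imprinted_file and Path(config.imprinted_file).exists()
        else {}
    )
    for name, df in reads.items():
        log.info("loaded %d %s reads", len(df), name)

    grid = windows.make_windows(chrom_sizes, config.window_width)
    stats = {
        cond: _condition_stats(
            cond, df, grid, cpgs, chrom_sizes, config, config.seed + i
        )
        for i, (cond, df) in enumerate(reads.items())
    }

    qc_block = {
        cond: {
            "saturation_estimated": s["saturation"].saturation,
            "saturation_truncated": s["saturation"].truncated_saturation,
            "cpg_enrichment": s["cpg_enrichment"],
            "cpg_coverage_fraction": s["cpg_coverage_fraction"],
            "library_total": s["track"].library_total,
            "covered_window_fraction": s["covered"].fraction,
        }
        for cond, s in stats.items()
    }
    for cond, s in stats.items():
        s["saturation"].to_frame().to_csv(
            out / f"saturation_{cond}.tsv", sep="\t", index=False
        )
        io.write_track(grid, s["track"].counts, out / f"counts_{cond}.bedgraph")
        io.write_track(grid, s["rpkm"].values, out / f"rpkm_{cond}.bedgraph")

    promoters = annotate.build_promoters(genes, config.promoter_upstream, chrom_sizes)
    tts = annotate.build_tts_regions(genes, config.tts_width, chrom_sizes)

    cov_block: dict[str, Any] = {"total_windows": grid.total_windows}
    chrom_tables, part_tables, strata_tables = [], [], []
    for cond, s in stats.items():
        ct = coverage.chromosome_coverage_table(s["covered"])
        ct["condition"] = cond
        chrom_tables.append(ct)
        pt = coverage.gene_part_coverage_table(s["covered"], genes, promoters, tts)
        pt["condition"] = cond
        part_tables.append(pt)
        st = coverage.cpg_density_strata(grid, cpgs, s["covered"], s["rpkm"])
        st["condition"] = cond
        strata_tables.append(st)
        n_cgi, f_cgi = coverage.element_capture(s["covered"], cgis)
        n_rep, f_rep = coverage.element_capture(s["covered"], repeats)
        n_prom, f_prom, mean_rpkm = coverage.promoter_rpkm_summary(
            s["rpkm"], s["covered"], promoters
        )
        cov_block[cond] = {
            "cgi_captured": n_cgi,
            "cgi_fraction": f_cgi,
            "repeat_captured": n_rep,
            "repeat_fraction": f_rep,
            "promoters_covered": n_prom,
            "promoter_fraction": f_prom,
            "promoter_mean_rpkm": mean_rpkm,
        }
    cov_block["per_chromosome"] = pd.concat(chrom_tables, ignore_index=True)
    cov_block["gene_parts"] = pd.concat(part_tables, ignore_index=True)
    cov_block["cpg_strata"] = pd.concat(strata_tables, ignore_index=True)
    cov_block["per_chromosome"].to_csv(out / "coverage_chromosomes.tsv", sep="\t", index=False)
    cov_block["gene_parts"].to_csv(out / "coverage_gene_parts.tsv", sep="\t", index=False)
    cov_block["cpg_strata"].to_csv(out / "cpg_strata.tsv", sep="\t", index=False)

    metagene_sets = {
        name: ids
        for name, ids in gene_sets.items()
        if name in ("expressed", "highly_expressed", "repressed")
    } or None
    meta = coverage.metagene_profile(
        stats["exposed"]["rpkm"], genes, metagene_sets,
        window=config.metagene_window, bin_size=config.metagene_bin,
    )
    meta.to_csv(out / "metagene_exposed.tsv", sep="\t", index=False)
    cov_block["metagene"] = meta

    params = ExactTestParams(
        dispersion=config.dispersion,
        p_threshold=config.p_threshold,
        min_total_count=config.min_total_count,
    )
    dhmrs = call_dhmrs(stats["control"]["track"], stats["exposed"]["track"], params)
    n_hyper = int((dhmrs["direction"] == "hyper").sum())
    n_hypo = int((dhmrs["direction"] == "hypo").sum())
    dhmr_block = {
        "total": len(dhmrs),
        "hyper": n_hyper,
        "hypo": n_hypo,
        "mean_rpkm_case": float(dhmrs["rpkm_case"].mean()) if len(dhmrs) else float("nan"),
        "mean_rpkm_control": float(dhmrs["rpkm_control"].mean()) if len(dhmrs) else float("nan"),
    }

    index = annotate.AnnotationIndex.build(genes, promoters, tts)
    annotated = annotate.assign_primary_feature(dhmrs, index)
    annotated = annotate.assign_repeat_classes(annotated, repeats)
    annotated.to_csv(out / "dhmrs.tsv", sep="\t", index=False)
    gene_table = annotate.dhmrs_to_genes(dhmrs, genes, promoters)
    gene_table.to_csv(out / "dhmr_genes.tsv", sep="\t", index=False)
    gene_summary = annotate.affected_gene_summary(gene_table)
    imprinted_flags = annotate.flag_imprinted_promoters(dhmrs, promoters, imprinted)
    imprinted_flags.to_csv(out / "imprinted_flags.tsv", sep="\t", index=False)
    feature_dist = annotated["primary_feature"].value_counts().to_dict() if len(annotated) else {}
    annotation_block = {
        "feature_distribution": feature_dist,
        "gene_summary": gene_summary,
        "imprinted_flags": imprinted_flags,
    }

    universe = [g.gene_id for g in genes]
    affected = gene_table["gene_id"].tolist()
    report_sets = {name: ids for name, ids in gene_sets.items()}
    enr_table = enrichment.overlap_report(affected, report_sets, universe)
    enr_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    benchmark = None
    if config.truth is not None and Path(config.truth).exists():
        truth = pd.read_csv(config.truth, sep="\t")
        benchmark = benchmark_against_truth(dhmrs, truth)

    report = RunReport(
        qc=qc_block,
        coverage=cov_block,
        dhmr=dhmr_block,
        annotation=annotation_block,
        enrichment=enr_table,
        benchmark=benchmark,
    )
    report.check_consistency()
    with open(out / "report.json", "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2, default=float)
    return report


def benchmark_against_truth(dhmrs: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Recovery of planted windows: recall, direction accuracy, precision proxy."""
    called = {
        (r.chrom, r.start): r.direction for r in dhmrs.itertuples()
    }
    n_truth = len(truth)
    recovered = 0
    direction_ok = 0
    by_direction = {"hyper": [0, 0], "hypo": [0, 0]}  # [recovered, planted]
    for r in truth.itertuples():
        by_direction[r.direction][1] += 1
        d = called.get((r.chrom, r.start))
        if d is not None:
            recovered += 1
            by_direction[r.direction][0] += 1
            if d == r.direction:
                direction_ok += 1
    truth_keys = {(r.chrom, r.start) for r in truth.itertuples()}
    false_calls = sum(1 for k in called if k not in truth_keys)
    return {
        "planted": n_truth,
        "recovered": recovered,
        "recall": recovered / n_truth if n_truth else float("nan"),
        "recall_hyper": (
            by_direction["hyper"][0] / by_direction["hyper"][1]
            if by_direction["hyper"][1]
            else float("nan")
        ),
        "recall_hypo": (
            by_direction["hypo"][0] / by_direction["hypo"][1]
            if by_direction["hypo"][1]
            else float("nan")
        ),
        "direction_accuracy": direction_ok / recovered if recovered else float("nan"),
        "called_total": len(dhmrs),
        "called_outside_truth": false_calls,
    }
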