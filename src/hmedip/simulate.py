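"""Deterministic toy genome and two-condition hMeDIP-seq read simulator.

No public 5hmC immunoprecipitation dataset ships with this package, so every
downstream stage is exercised on simulated data with known ground truth.
The simulator builds a small genome with the annotation layers the analyses
need (gene models with promoter/UTR/exon/intron/TTS parts, CpG sites with
CpG-island clusters, labelled repeat classes, expression/histone-mark/
imprinted gene sets), plants hyper- and hypo-hydroxymethylated 100-bp
windows with a known fold change, and draws 51-bp reads under a
negative-binomial count model per window.

The count model matches the exact test used by the caller: window counts
are NB with variance ``mu + phi*mu**2`` (gamma-Poisson mixture), Poisson
when ``phi == 0``. The control library has mean ``depth_per_window`` per
window; the exposed library has mean ``depth * library_size_ratio`` at
background windows (a pure library-size effect that normalisation removes)
and ``depth * fold_change`` / ``depth / fold_change`` at planted hyper /
hypo windows, so the *raw* exposed:control mean ratio at planted windows
equals ``fold_change``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .windows import WindowGrid, make_windows

__all__ = [
    "SimulationConfig",
    "GeneModel",
    "ToyGenome",
    "PlantedSignal",
    "build_toy_genome",
    "plant_dhmr_signals",
    "simulate_window_counts",
    "simulate_reads",
    "write_fixtures",
    "load_fixtures",
]

#: transcriptional order of gene parts; each gene has 3 exons and 2 introns
GENE_PART_ORDER = (
    "five_prime_utr",
    "exon",
    "intron",
    "exon",
    "intron",
    "exon",
    "three_prime_utr",
)

#: library sizes of the pooled control / exposed sperm libraries this
#: simulator is scaled after (the ratio, not the absolute depth, matters)
CONTROL_LIBRARY_READS = 35_995_280
EXPOSED_LIBRARY_READS = 44_263_854


@dataclass
class SimulationConfig:
    """All knobs of the toy genome and the read simulator.

    Defaults are a desk-scale preset: 2 chromosomes x 500 kb = 10,000
    100-bp windows at depth 10, so a full pipeline run takes seconds while
    keeping per-window counts in the regime of a real ~0.7x-per-window
    genome-wide library.
    """

    seed: int = 0
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 500_000}
    )
    n_genes: int = 60
    gene_part_lengths: Mapping[str, int] = field(
        default_factory=lambda: {
            "five_prime_utr": 200,
            "exon": 300,
            "intron": 700,
            "three_prime_utr": 300,
        }
    )
    n_cgis: int = 20
    cgi_length: int = 800
    cgi_cpg_per_100bp: float = 10.0
    background_cpg_per_100bp: float = 1.0
    repeat_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"LINE": 0.10, "SINE": 0.08, "LTR": 0.04, "DNA": 0.03}
    )
    read_length: int = 51
    depth_per_window: float = 10.0
    dispersion: float = 0.05
    n_hyper: int = 50
    n_hypo: int = 10
    fold_change: float = 4.0
    library_size_ratio: float = EXPOSED_LIBRARY_READS / CONTROL_LIBRARY_READS
    window_width: int = 100
    promoter_upstream: int = 2000
    tts_width: int = 1000

    def validate(self) -> None:
        if self.n_genes < 0 or self.n_cgis < 0 or self.n_hyper < 0 or self.n_hypo < 0:
            raise ConfigError("counts must be non-negative")
        if self.fold_change <= 1:
            raise ConfigError(f"fold_change must be > 1, got {self.fold_change}")
        if self.dispersion < 0:
            raise ConfigError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.depth_per_window < 0:
            raise ConfigError(f"depth_per_window must be >= 0, got {self.depth_per_window}")
        if self.cgi_cpg_per_100bp < 0 or self.background_cpg_per_100bp < 0:
            raise ConfigError("CpG densities must be >= 0")
        if self.read_length <= 0 or self.window_width <= 0:
            raise ConfigError("read_length and window_width must be > 0")
        grid = make_windows(self.chrom_sizes, self.window_width)
        if self.n_hyper + self.n_hypo > grid.total_windows:
            raise ConfigError(
                f"requested {self.n_hyper + self.n_hypo} planted windows but the "
                f"grid only has {grid.total_windows}"
            )

    @property
    def gene_span(self) -> int:
        return sum(self.gene_part_lengths[p] for p in GENE_PART_ORDER)

    def grid(self) -> WindowGrid:
        return make_windows(self.chrom_sizes, self.window_width)


@dataclass
class GeneModel:
    """One canonical transcript: genomic extent, strand, TSS and labelled parts."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    start: int  # 0-based half-open genomic extent of the transcribed unit
    end: int
    parts: list[tuple[str, int, int]]  # (label, start, end), genomic coords

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class ToyGenome:
    """Simulated genome plus every annotation layer the analyses use."""

    chrom_sizes: dict[str, int]
    cpg_positions: dict[str, np.ndarray]
    gene_models: list[GeneModel]
    cgis: pd.DataFrame  # chrom, start, end, name
    repeats: pd.DataFrame  # chrom, start, end, repeat_class
    imprinted_origin: dict[str, str]  # gene_id -> maternal/paternal
    expressed_ids: set[str]
    highly_expressed_ids: set[str]
    repressed_ids: set[str]
    h3k4me2_ids: set[str]
    h3k4me3_ids: set[str]
    h3k27me3_ids: set[str]

    @property
    def imprinted_ids(self) -> set[str]:
        return set(self.imprinted_origin)

    @property
    def bivalent_ids(self) -> set[str]:
        return self.h3k4me3_ids & self.h3k27me3_ids

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.gene_models]

    def gene_sets(self) -> dict[str, set[str]]:
        return {
            "expressed": set(self.expressed_ids),
            "highly_expressed": set(self.highly_expressed_ids),
            "repressed": set(self.repressed_ids),
            "h3k4me2": set(self.h3k4me2_ids),
            "h3k4me3": set(self.h3k4me3_ids),
            "h3k27me3": set(self.h3k27me3_ids),
            "bivalent": set(self.bivalent_ids),
            "imprinted": set(self.imprinted_ids),
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, ToyGenome):
            return NotImplemented
        same_cpgs = self.cpg_positions.keys() == other.cpg_positions.keys() and all(
            np.array_equal(self.cpg_positions[c], other.cpg_positions[c])
            for c in self.cpg_positions
        )
        return (
            self.chrom_sizes == other.chrom_sizes
            and same_cpgs
            and self.gene_models == other.gene_models
            and self.cgis.reset_index(drop=True).equals(other.cgis.reset_index(drop=True))
            and self.repeats.reset_index(drop=True).equals(
                other.repeats.reset_index(drop=True)
            )
            and self.imprinted_origin == other.imprinted_origin
            and self.expressed_ids == other.expressed_ids
            and self.highly_expressed_ids == other.highly_expressed_ids
            and self.repressed_ids == other.repressed_ids
            and self.h3k4me2_ids == other.h3k4me2_ids
            and self.h3k4me3_ids == other.h3k4me3_ids
            and self.h3k27me3_ids == other.h3k27me3_ids
        )


@dataclass
class PlantedSignal:
    """Ground-truth table of simulated differential windows."""

    records: pd.DataFrame  # chrom, start, end, direction, fold_change

    def __post_init__(self) -> None:
        cols = ["chrom", "start", "end", "direction", "fold_change"]
        if list(self.records.columns) != cols:
            self.records = self.records.reindex(columns=cols)

    def __len__(self) -> int:
        return len(self.records)

    def window_multipliers(
        self, grid: WindowGrid, ratio: float = 1.0
    ) -> np.ndarray:
        """Exposed-library per-window mean multipliers relative to depth.

        Background windows get ``ratio`` (the library-size effect); planted
        hyper windows ``fold`` and hypo windows ``1/fold``.
        """
        mult = np.full(grid.total_windows, ratio)
        for rec in self.records.itertuples():
            k = grid.offset(rec.chrom) + rec.start // grid.width
            mult[k] = rec.fold_change if rec.direction == "hyper" else 1.0 / rec.fold_change
        return mult

    def __eq__(self, other) -> bool:
        if not isinstance(other, PlantedSignal):
            return NotImplemented
        return self.records.reset_index(drop=True).equals(
            other.records.reset_index(drop=True)
        )


def _derive_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def build_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Deterministically build the toy genome for a configuration.

    Gene models are placed without overlap, leaving room for the implied
    upstream promoter and downstream TTS region; roughly half the CpG
    islands sit on promoters (as in real genomes) and the rest in the
    background. Gene sets are drawn with controlled overlaps: highly
    expressed genes are a subset of expressed genes, repressed genes are
    disjoint from them, and the bivalent set is the forced intersection of
    the H3K4me3 and H3K27me3 sets.
    """
    config.validate()
    rng = _derive_rng(config.seed, 0)
    chroms = list(config.chrom_sizes)

    genes = _place_genes(config, rng)
    cgis = _place_cgis(config, genes, rng)
    cpgs = _place_cpgs(config, cgis, rng)
    repeats = _place_repeats(config, rng)
    sets = _draw_gene_sets(config, [g.gene_id for g in genes], rng)

    for g in genes:
        if g.end > config.chrom_sizes[g.chrom]:
            raise ConfigError(
                f"gene {g.gene_id} extends past the end of {g.chrom}: "
                f"reduce gene_part_lengths or enlarge the chromosome"
            )

    return ToyGenome(
        chrom_sizes=dict(config.chrom_sizes),
        cpg_positions=cpgs,
        gene_models=genes,
        cgis=cgis,
        repeats=repeats,
        **sets,
    )


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    chroms = list(config.chrom_sizes)
    span = config.gene_span
    footprint = config.promoter_upstream + span + config.tts_width
    genes: list[GeneModel] = []
    # spread genes across chromosomes proportionally to length
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    per_chrom = np.floor(config.n_genes * sizes / sizes.sum()).astype(int)
    per_chrom[: config.n_genes - per_chrom.sum()] += 1
    gi = 0
    for chrom, n_here in zip(chroms, per_chrom):
        size = config.chrom_sizes[chrom]
        if n_here == 0:
            continue
        slot = size // n_here
        if slot < footprint + 200:
            raise ConfigError(
                f"gene footprint {footprint} bp does not fit {n_here} genes "
                f"on {chrom} (length {size}); offending gene gene_{gi:04d}"
            )
        for j in range(n_here):
            jitter = int(rng.integers(0, max(1, slot - footprint - 100)))
            tx_start = j * slot + config.promoter_upstream + jitter
            strand = "+" if rng.random() < 0.5 else "-"
            order = (
                GENE_PART_ORDER if strand == "+" else tuple(reversed(GENE_PART_ORDER))
            )
            parts, pos = [], tx_start
            for label in order:
                length = config.gene_part_lengths[label]
                parts.append((label, pos, pos + length))
                pos += length
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gi:04d}",
                    chrom=chrom,
                    strand=strand,
                    start=tx_start,
                    end=pos,
                    parts=parts,
                )
            )
            gi += 1
    return genes


def _place_cgis(
    config: SimulationConfig, genes: list[GeneModel], rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    n_promoter = min(config.n_cgis // 2, len(genes))
    promoter_genes = rng.choice(len(genes), size=n_promoter, replace=False) if n_promoter else []
    taken: list[tuple[str, int, int]] = []
    for idx in promoter_genes:
        g = genes[idx]
        if g.strand == "+":
            start = max(0, g.tss - config.cgi_length // 2)
        else:
            start = min(config.chrom_sizes[g.chrom], g.tss + config.cgi_length // 2) - config.cgi_length
            start = max(0, start)
        rows.append((g.chrom, start, start + config.cgi_length))
        taken.append((g.chrom, start, start + config.cgi_length))
    chroms = list(config.chrom_sizes)
    tries = 0
    while len(rows) < config.n_cgis and tries < 10_000:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, config.chrom_sizes[chrom] - config.cgi_length))
        cand = (chrom, start, start + config.cgi_length)
        if any(c == cand[0] and cand[1] < e and s < cand[2] for c, s, e in taken):
            continue
        rows.append(cand)
        taken.append(cand)
    if len(rows) < config.n_cgis:
        raise ConfigError("could not place the requested number of CpG islands")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    df["name"] = [f"cgi_{i:04d}" for i in range(len(df))]
    return df


def _place_cpgs(
    config: SimulationConfig, cgis: pd.DataFrame, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    cpgs: dict[str, np.ndarray] = {}
    for chrom, size in config.chrom_sizes.items():
        positions: list[np.ndarray] = []
        # background: Poisson per 100-bp window, uniform placement
        n_win = -(-size // 100)
        bg_counts = rng.poisson(config.background_cpg_per_100bp, size=n_win)
        for k in np.nonzero(bg_counts)[0]:
            w_start = k * 100
            w_end = min(w_start + 100, size)
            positions.append(
                rng.integers(w_start, w_end, size=bg_counts[k]).astype(np.int64)
            )
        # CGIs: dense, deterministic even spacing so the density floor holds
        for cgi in cgis[cgis["chrom"] == chrom].itertuples():
            length = cgi.end - cgi.start
            n_sites = int(np.ceil(length / 100 * config.cgi_cpg_per_100bp))
            if n_sites:
                step = length / n_sites
                positions.append(
                    (cgi.start + np.floor(np.arange(n_sites) * step)).astype(np.int64)
                )
        if positions:
            pos = np.unique(np.concatenate(positions))
            pos = pos[(pos >= 0) & (pos < size)]
        else:
            pos = np.empty(0, dtype=np.int64)
        cpgs[chrom] = pos
    return cpgs


def _place_repeats(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, size in config.chrom_sizes.items():
        for klass, frac in config.repeat_fraction.items():
            target = frac * size
            placed = 0.0
            cursor = int(rng.integers(0, 2000))
            while placed < target and cursor < size - 300:
                length = int(rng.integers(300, 1501))
                end = min(cursor + length, size)
                rows.append((chrom, cursor, end, klass))
                placed += end - cursor
                remaining = max(1.0, target - placed)
                # expected gap so the class lands near its target fraction
                mean_gap = max(500.0, (size - cursor) * (1 - frac) / max(1.0, remaining / 900.0) * 0.02)
                cursor = end + int(rng.exponential(mean_gap))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_class"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _draw_gene_sets(
    config: SimulationConfig, gene_ids: list[str], rng: np.random.Generator
) -> dict:
    ids = np.array(gene_ids)
    n = len(ids)

    def sample(pool: np.ndarray, k: int) -> set[str]:
        k = min(k, len(pool))
        return set(rng.choice(pool, size=k, replace=False)) if k else set()

    expressed = sample(ids, n // 2)
    highly = sample(np.array(sorted(expressed)), max(1, n // 10))
    not_expressed = np.array(sorted(set(ids) - expressed))
    repressed = sample(not_expressed, max(1, n // 6))
    k4me3 = sample(ids, max(1, n // 4))
    # forced fixed-size bivalent intersection
    bivalent = sample(np.array(sorted(k4me3)), max(1, n // 12))
    k27_extra = sample(np.array(sorted(set(ids) - k4me3)), max(1, n // 10))
    k27me3 = bivalent | k27_extra
    k4me2 = sample(ids, max(1, n // 3)) | k4me3
    imprinted_pool = sorted(sample(ids, max(2, n // 10)))
    origins = {}
    for i, gid in enumerate(imprinted_pool):
        origins[gid] = "maternal" if i % 2 == 0 else "paternal"
    return {
        "expressed_ids": expressed,
        "highly_expressed_ids": highly,
        "repressed_ids": repressed,
        "h3k4me2_ids": k4me2,
        "h3k4me3_ids": k4me3,
        "h3k27me3_ids": k27me3,
        "imprinted_origin": origins,
    }


def plant_dhmr_signals(genome: ToyGenome, config: SimulationConfig) -> PlantedSignal:
    """Choose disjoint grid windows to carry hyper/hypo differential signal."""
    config.validate()
    rng = _derive_rng(config.seed, 1)
    grid = make_windows(genome.chrom_sizes, config.window_width)
    # only full-width windows are candidates, so planted intervals are exact
    candidates = []
    for chrom in grid.chroms:
        starts, ends = grid.window_bounds(chrom)
        full = ends - starts == grid.width
        candidates.extend((chrom, int(s)) for s in starts[full])
    n_needed = config.n_hyper + config.n_hypo
    if n_needed > len(candidates):
        raise DataError(
            f"requested {n_needed} planted windows, only {len(candidates)} available"
        )
    chosen = rng.choice(len(candidates), size=n_needed, replace=False)
    rows = []
    for i, ci in enumerate(chosen):
        chrom, start = candidates[ci]
        direction = "hyper" if i < config.n_hyper else "hypo"
        rows.append((chrom, start, start + grid.width, direction, config.fold_change))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "fold_change"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return PlantedSignal(df)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + phi*mu^2; Poisson at phi=0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_window_counts(
    genome: ToyGenome,
    signal: PlantedSignal,
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw the per-window NB counts for one condition (the count model itself).

    This is the distribution the DhMR caller's exact test assumes; it is
    also what :func:`simulate_reads` expands into read intervals. Note that
    downstream *overlap counting* of the emitted reads adds boundary
    spillover from neighbouring windows on top of these draws.
    """
    if condition not in ("control", "exposed"):
        raise ConfigError(f"condition must be control or exposed, got {condition!r}")
    if config.depth_per_window < 0:
        raise ConfigError("depth_per_window must be >= 0")
    if rng is None:
        rng = _derive_rng(config.seed, 2 if condition == "control" else 3)
    grid = make_windows(genome.chrom_sizes, config.window_width)
    if condition == "control":
        means = np.full(grid.total_windows, config.depth_per_window)
    else:
        means = config.depth_per_window * signal.window_multipliers(
            grid, ratio=config.library_size_ratio
        )
    return _nb_counts(rng, means, config.dispersion)


def simulate_reads(
    genome: ToyGenome,
    signal: PlantedSignal,
    config: SimulationConfig,
    condition: str,
) -> pd.DataFrame:
    """Draw a BED6-like read table for one condition.

    Per-window counts are NB(mean, dispersion); read start positions are
    uniform within the window, so reads overhang window boundaries exactly
    as real short reads do (the counting stage must handle this).
    """
    rng = _derive_rng(config.seed, 2 if condition == "control" else 3)
    counts = simulate_window_counts(genome, signal, config, condition, rng=rng)
    grid = make_windows(genome.chrom_sizes, config.window_width)
    frames = []
    for chrom in grid.chroms:
        o = grid.offset(chrom)
        n = grid.n_windows(chrom)
        c = counts[o : o + n]
        starts_w, _ = grid.window_bounds(chrom)
        win_of_read = np.repeat(np.arange(n), c)
        if len(win_of_read) == 0:
            continue
        offsets = rng.integers(0, grid.width, size=len(win_of_read))
        starts = starts_w[win_of_read] + offsets
        max_start = genome.chrom_sizes[chrom] - config.read_length
        starts = np.clip(starts, 0, max_start)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.sort(starts),
                    "end": np.sort(starts) + config.read_length,
                }
            )
        )
    if not frames:
        reads = pd.DataFrame(columns=["chrom", "start", "end"])
    else:
        reads = pd.concat(frames, ignore_index=True)
    reads["name"] = [f"{condition}_read_{i}" for i in range(len(reads))]
    reads["score"] = 60
    strands = np.array(["+", "-"])
    reads["strand"] = strands[
        rng.integers(0, 2, size=len(reads))
    ] if len(reads) else np.empty(0, dtype=object)
    reads["start"] = reads["start"].astype(np.int64) if len(reads) else reads["start"]
    return reads


# ---------------------------------------------------------------------------
# fixture bundle I/O


def write_fixtures(
    genome: ToyGenome,
    signal: PlantedSignal,
    reads: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Serialise every simulated artefact as plain-text files.

    Emits chrom.sizes (TSV), genes.gff (GFF3, 1-based closed), cgis.bed /
    repeats.bed / cpg.bed (0-based half-open BED), reads_<condition>.bed
    (BED6), truth.tsv and one geneset_<name>.txt per gene set (the
    imprinted list carries a second parent-of-origin column). Reading the
    bundle back with :func:`load_fixtures` reproduces the in-memory objects.
    """
    from . import io as hio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = out / "chrom.sizes"
    hio.write_chrom_sizes(genome.chrom_sizes, paths["chrom_sizes"])

    paths["genes"] = out / "genes.gff"
    hio.write_gene_models_gff(genome.gene_models, paths["genes"])

    paths["cgis"] = out / "cgis.bed"
    hio.write_bed(genome.cgis[["chrom", "start", "end", "name"]], paths["cgis"])

    paths["repeats"] = out / "repeats.bed"
    hio.write_bed(
        genome.repeats.rename(columns={"repeat_class": "name"}), paths["repeats"]
    )

    paths["cpg"] = out / "cpg.bed"
    cpg_rows = []
    for chrom, pos in genome.cpg_positions.items():
        cpg_rows.append(pd.DataFrame({"chrom": chrom, "start": pos, "end": pos + 2}))
    cpg_df = (
        pd.concat(cpg_rows, ignore_index=True)
        if cpg_rows
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    hio.write_bed(cpg_df, paths["cpg"])

    for cond, df in reads.items():
        paths[f"reads_{cond}"] = out / f"reads_{cond}.bed"
        hio.write_bed(df, paths[f"reads_{cond}"])

    paths["truth"] = out / "truth.tsv"
    signal.records.to_csv(paths["truth"], sep="\t", index=False)

    for name, ids in genome.gene_sets().items():
        if name in ("imprinted", "bivalent"):
            continue  # imprinted written with labels below; bivalent is derived
        p = out / f"geneset_{name}.txt"
        p.write_text("".join(f"{g}\n" for g in sorted(ids)))
        paths[f"geneset_{name}"] = p
    p = out / "geneset_imprinted.txt"
    p.write_text(
        "".join(f"{g}\t{o}\n" for g, o in sorted(genome.imprinted_origin.items()))
    )
    paths["geneset_imprinted"] = p
    return paths


def load_fixtures(fixture_dir: str | Path) -> tuple[ToyGenome, PlantedSignal, dict[str, pd.DataFrame]]:
    """Inverse of :func:`write_fixtures`."""
    from . import io as hio

    d = Path(fixture_dir)
    chrom_sizes = hio.read_chrom_sizes(d / "chrom.sizes")
    genes = hio.read_gene_models_gff(d / "genes.gff")
    cgis = hio.read_bed(d / "cgis.bed", names=["chrom", "start", "end", "name"])
    repeats = hio.read_bed(d / "repeats.bed", names=["chrom", "start", "end", "name"])
    repeats = repeats.rename(columns={"name": "repeat_class"})
    cpg_df = hio.read_bed(d / "cpg.bed", names=["chrom", "start", "end"])
    cpgs = {
        chrom: np.sort(g["start"].to_numpy(dtype=np.int64))
        for chrom, g in cpg_df.groupby("chrom", sort=False)
    }
    for chrom in chrom_sizes:
        cpgs.setdefault(chrom, np.empty(0, dtype=np.int64))
    sets: dict[str, set[str]] = {}
    for name in ("expressed", "highly_expressed", "repressed", "h3k4me2", "h3k4me3", "h3k27me3"):
        sets[f"{name}_ids"] = set(
            (d / f"geneset_{name}.txt").read_text().split()
        )
    imprinted: dict[str, str] = {}
    for line in (d / "geneset_imprinted.txt").read_text().splitlines():
        if line.strip():
            gid, origin = line.split("\t")
            imprinted[gid] = origin
    genome = ToyGenome(
        chrom_sizes=chrom_sizes,
        cpg_positions=cpgs,
        gene_models=genes,
        cgis=cgis,
        repeats=repeats,
        imprinted_origin=imprinted,
        **sets,
    )
    truth = pd.read_csv(d / "truth.tsv", sep="\t")
    signal = PlantedSignal(truth)
    reads = {}
    for cond in ("control", "exposed"):
        p = d / f"reads_{cond}.bed"
        if p.exists():
            reads[cond] = hio.read_bed(
                p, names=["chrom", "start", "end", "name", "score", "strand"]
            )
    return genome, signal, reads
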