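"""Fixed-width genome windows: counting, RPKM, covered regions and library QC.

The whole pipeline is indexed on a :class:`WindowGrid` — a partition of every
chromosome into fixed-width bins (100 bp by default). Reads are counted by
overlap (a read increments every window it touches by at least one base), so
the column sum of a count track can exceed the number of input reads; the
``library_total`` attribute always equals the number of reads and is the
quantity used for RPKM and size-factor normalisation.

Two immunoprecipitation QC statistics are provided:

* :func:`saturation_analysis` — split-half correlation of window counts at
  increasing subsample fractions, with a resampling-doubled "estimated"
  variant used as the headline saturation number.
* :func:`cpg_enrichment_score` — CpG density inside read-covered bases
  relative to the genome-wide CpG density (relH-style); a successful
  (hydroxy)methyl enrichment gives a score above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "WindowGrid",
    "WindowCountTrack",
    "RpkmTrack",
    "CoveredWindowSet",
    "SaturationResult",
    "make_windows",
    "count_reads",
    "to_rpkm",
    "covered_windows",
    "saturation_analysis",
    "cpg_enrichment_score",
]


@dataclass(frozen=True)
class WindowGrid:
    """Partition of a genome into fixed-width windows.

    Windows on chromosome ``c`` of length ``L`` are the half-open intervals
    ``[k*width, min((k+1)*width, L))`` for ``k = 0 .. ceil(L/width)-1``; the
    final window may be shorter than ``width``. Windows across chromosomes
    are laid out in one flat index in chromosome order.
    """

    chrom_sizes: Mapping[str, int]
    width: int = 100
    _offsets: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"window width must be > 0, got {self.width}")
        offsets, pos = {}, 0
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ConfigError(f"chromosome {chrom} has non-positive length {size}")
            offsets[chrom] = pos
            pos += -(-size // self.width)
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "chrom_sizes", dict(self.chrom_sizes))

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_windows(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.width)

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows(c) for c in self.chroms)

    def offset(self, chrom: str) -> int:
        """Flat index of the first window of ``chrom``."""
        return self._offsets[chrom]

    def window_lengths(self, chrom: str) -> np.ndarray:
        n, size = self.n_windows(chrom), self.chrom_sizes[chrom]
        lens = np.full(n, self.width, dtype=np.int64)
        lens[-1] = size - (n - 1) * self.width
        return lens

    def all_window_lengths(self) -> np.ndarray:
        return np.concatenate([self.window_lengths(c) for c in self.chroms])

    def window_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_windows(chrom)
        starts = np.arange(n, dtype=np.int64) * self.width
        ends = np.minimum(starts + self.width, self.chrom_sizes[chrom])
        return starts, ends

    def to_frame(self) -> pd.DataFrame:
        """All windows as a BED-like frame (chrom, start, end)."""
        parts = []
        for chrom in self.chroms:
            starts, ends = self.window_bounds(chrom)
            parts.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(parts, ignore_index=True)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WindowGrid)
            and self.width == other.width
            and dict(self.chrom_sizes) == dict(other.chrom_sizes)
        )


@dataclass
class WindowCountTrack:
    """Per-window read counts plus the library size used for normalisation."""

    grid: WindowGrid
    counts: np.ndarray
    library_total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.grid.total_windows,):
            raise DataError(
                f"count vector length {self.counts.shape} does not match "
                f"grid with {self.grid.total_windows} windows"
            )
        if (self.counts < 0).any():
            raise DataError("window counts must be non-negative")


@dataclass
class RpkmTrack:
    """Per-window RPKM: count / (window_kb * library_millions)."""

    grid: WindowGrid
    values: np.ndarray
    library_total: int


@dataclass
class CoveredWindowSet:
    """Windows overlapped by at least one read (count >= 1)."""

    grid: WindowGrid
    mask: np.ndarray

    @property
    def covered_count(self) -> int:
        return int(self.mask.sum())

    @property
    def fraction(self) -> float:
        return self.covered_count / self.grid.total_windows

    def chrom_mask(self, chrom: str) -> np.ndarray:
        o = self.grid.offset(chrom)
        return self.mask[o : o + self.grid.n_windows(chrom)]


def make_windows(chrom_sizes: Mapping[str, int], width: int = 100) -> WindowGrid:
    """Tile each chromosome with ``width``-bp windows (last one truncated)."""
    return WindowGrid(chrom_sizes, width)


def _reads_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    return pd.DataFrame(list(reads), columns=["chrom", "start", "end"])


def count_reads(
    grid: WindowGrid,
    reads,
    min_mapq: float | None = None,
) -> WindowCountTrack:
    """Count reads per window; a read increments every window it overlaps.

    Parameters
    ----------
    reads
        BED-like frame with ``chrom``, ``start``, ``end`` columns
        (0-based half-open), or an iterable of such triples.
    min_mapq
        If given and the frame has a ``score`` column, drop reads with
        score below this threshold before counting (alignment-quality
        filtering as an I/O convenience).
    """
    df = _reads_frame(reads)
    if min_mapq is not None and "score" in df.columns:
        df = df[pd.to_numeric(df["score"], errors="coerce") >= min_mapq]
    counts = np.zeros(grid.total_windows, dtype=np.int64)
    unknown = set(df["chrom"].unique()) - set(grid.chroms)
    if unknown:
        raise DataError(f"reads on unknown chromosome(s): {sorted(unknown)}")
    w = grid.width
    for chrom, group in df.groupby("chrom", sort=False):
        starts = group["start"].to_numpy(dtype=np.int64)
        ends = group["end"].to_numpy(dtype=np.int64)
        if (starts < 0).any() or (ends > grid.chrom_sizes[chrom]).any():
            raise DataError(f"read outside bounds of chromosome {chrom}")
        if (ends <= starts).any():
            raise DataError(f"empty or inverted read interval on {chrom}")
        first = starts // w
        last = (ends - 1) // w
        o = grid.offset(chrom)
        span = int((last - first).max()) if len(first) else 0
        for d in range(span + 1):
            idx = first + d
            sel = idx <= last
            np.add.at(counts, o + idx[sel], 1)
    return WindowCountTrack(grid, counts, library_total=len(df))


def to_rpkm(track: WindowCountTrack, grid: WindowGrid | None = None) -> RpkmTrack:
    """Reads per kilobase of window per million mapped reads.

    Uses each window's actual length, so the truncated final window of a
    chromosome is normalised by its true size.
    """
    grid = grid or track.grid
    if track.library_total <= 0:
        raise DataError("RPKM undefined for an empty library (library_total == 0)")
    kb = grid.all_window_lengths() / 1000.0
    millions = track.library_total / 1e6
    return RpkmTrack(grid, track.counts / (kb * millions), track.library_total)


def covered_windows(track: WindowCountTrack) -> CoveredWindowSet:
    """Windows covered by >= 1 read (the any-part, one-read rule)."""
    return CoveredWindowSet(track.grid, track.counts >= 1)


@dataclass
class SaturationResult:
    """Split-half saturation curve and headline estimate.

    ``truncated`` correlates growing subsets of one random half of the
    library against the fixed other half; ``estimated`` first doubles each
    subset by resampling reads with replacement, extrapolating what a
    library of twice the depth would give. ``saturation`` is the estimated
    correlation at the full-data step.
    """

    fractions: np.ndarray
    truncated: np.ndarray
    estimated: np.ndarray

    @property
    def saturation(self) -> float:
        return float(self.estimated[-1])

    @property
    def truncated_saturation(self) -> float:
        return float(self.truncated[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "truncated_correlation": self.truncated,
                "estimated_correlation": self.estimated,
            }
        )


def _window_counts(grid: WindowGrid, df: pd.DataFrame) -> np.ndarray:
    return count_reads(grid, df).counts


def saturation_analysis(
    reads,
    grid: WindowGrid,
    steps: int = 10,
    seed: int | np.random.Generator | None = None,
) -> SaturationResult:
    """Estimate whether sequencing depth saturates genome coverage.

    The reads are split at random into two halves A and B. For
    ``k = 1..steps`` the Pearson correlation between the window counts of
    the first ``k/steps`` of A and the counts of all of B is computed
    (truncated curve); the estimated curve doubles each subset of A by
    resampling with replacement before counting.
    """
    df = _reads_frame(reads).reset_index(drop=True)
    if len(df) < 2:
        raise DataError("saturation analysis needs at least 2 reads")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    perm = rng.permutation(len(df))
    half = len(df) // 2
    a_idx, b_idx = perm[:half], perm[half:]
    counts_b = _window_counts(grid, df.iloc[b_idx])
    fractions = np.arange(1, steps + 1) / steps
    trunc, est = np.empty(steps), np.empty(steps)
    for i, frac in enumerate(fractions):
        take = max(1, int(round(frac * half)))
        sub = a_idx[:take]
        counts_sub = _window_counts(grid, df.iloc[sub])
        trunc[i] = _pearson(counts_sub, counts_b)
        doubled = rng.choice(sub, size=2 * take, replace=True)
        est[i] = _pearson(_window_counts(grid, df.iloc[doubled]), counts_b)
    return SaturationResult(fractions, trunc, est)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x.astype(float)
    y = y.astype(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _covered_bases_and_cpgs(
    reads: pd.DataFrame, cpg_positions: Mapping[str, np.ndarray]
) -> tuple[int, int]:
    total_bases = 0
    total_cpgs = 0
    for chrom, group in reads.groupby("chrom", sort=False):
        starts = np.sort(group["start"].to_numpy(dtype=np.int64))
        order = np.argsort(group["start"].to_numpy(dtype=np.int64), kind="stable")
        s = group["start"].to_numpy(dtype=np.int64)[order]
        e = group["end"].to_numpy(dtype=np.int64)[order]
        # merge overlapping read intervals into a disjoint union
        merged_s, merged_e = [], []
        cur_s, cur_e = s[0], e[0]
        for i in range(1, len(s)):
            if s[i] <= cur_e:
                cur_e = max(cur_e, e[i])
            else:
                merged_s.append(cur_s)
                merged_e.append(cur_e)
                cur_s, cur_e = s[i], e[i]
        merged_s.append(cur_s)
        merged_e.append(cur_e)
        ms = np.asarray(merged_s)
        me = np.asarray(merged_e)
        total_bases += int((me - ms).sum())
        pos = np.asarray(cpg_positions.get(chrom, ()), dtype=np.int64)
        if len(pos):
            lo = np.searchsorted(pos, ms, side="left")
            hi = np.searchsorted(pos, me, side="left")
            total_cpgs += int((hi - lo).sum())
    return total_bases, total_cpgs


def cpg_enrichment_score(
    reads,
    cpg_positions: Mapping[str, np.ndarray],
    chrom_sizes: Mapping[str, int],
) -> float:
    """CpG density in read-covered bases over genome-wide CpG density.

    A CpG site is located by the position of its C on the forward strand.
    A score of 1 means the sequenced fraction of the genome is no more
    CpG-dense than the genome as a whole; methyl/hydroxymethyl capture
    protocols are expected to score above 1.
    """
    df = _reads_frame(reads)
    if len(df) == 0:
        raise DataError("CpG enrichment undefined with zero reads")
    genome_len = sum(chrom_sizes.values())
    genome_cpgs = sum(len(v) for v in cpg_positions.values())
    if genome_cpgs == 0:
        raise DataError("CpG enrichment undefined with zero genome CpGs")
    covered_bases, covered_cpgs = _covered_bases_and_cpgs(df, cpg_positions)
    if covered_bases == 0:
        raise DataError("CpG enrichment undefined with zero covered bases")
    return (covered_cpgs / covered_bases) / (genome_cpgs / genome_len)
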