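"""Coverage and ratio statistics over the covered-window landscape.

Everything here reduces to one of two rules applied to a
:class:`~hmedip.windows.CoveredWindowSet`:

* base-resolution ratios — what fraction of a target's bases falls inside
  covered windows (genome-wide, per chromosome, per gene-part union);
* element capture — an element (CpG island, promoter, repeat, ...) counts
  as captured as soon as any part of it overlaps a covered window by one
  base.

Plus two signal summaries: per-CpG-density-class statistics and
strand-aware six-bin metagene profiles around the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .windows import CoveredWindowSet, RpkmTrack, WindowGrid

__all__ = [
    "CoverageRatio",
    "coverage_ratio",
    "element_capture",
    "chromosome_coverage_table",
    "gene_part_coverage_table",
    "cpg_density_strata",
    "promoter_rpkm_summary",
    "metagene_profile",
    "classify_cpg_density",
    "merge_intervals",
]

CPG_CLASSES = ("low", "moderate", "high")


@dataclass(frozen=True)
class CoverageRatio:
    """Fraction of a target's bases lying inside covered windows."""

    name: str
    covered_bases: int
    total_bases: int

    @property
    def ratio(self) -> float:
        return self.covered_bases / self.total_bases


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly-overlapping intervals, per chromosome."""
    out = []
    for chrom, group in df.groupby("chrom", sort=False):
        g = group.sort_values("start")
        s = g["start"].to_numpy(dtype=np.int64)
        e = g["end"].to_numpy(dtype=np.int64)
        cur_s, cur_e = s[0], e[0]
        for i in range(1, len(s)):
            if s[i] <= cur_e:
                cur_e = max(cur_e, e[i])
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s[i], e[i]
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _covered_prefixes(covered: CoveredWindowSet, chrom: str):
    """Prefix sums of covered-window lengths and the covered mask for a chromosome."""
    grid = covered.grid
    mask = covered.chrom_mask(chrom)
    lens = grid.window_lengths(chrom)
    cum_bases = np.concatenate(([0], np.cumsum(lens * mask)))
    cum_mask = np.concatenate(([0], np.cumsum(mask.astype(np.int64))))
    return mask, cum_bases, cum_mask


def _covered_bases_in(covered: CoveredWindowSet, targets: pd.DataFrame) -> int:
    """Bases of the (already merged) targets inside covered windows."""
    grid = covered.grid
    w = grid.width
    total = 0
    for chrom, group in targets.groupby("chrom", sort=False):
        if chrom not in grid.chrom_sizes:
            raise DataError(f"target on unknown chromosome {chrom}")
        mask, cum_bases, _ = _covered_prefixes(covered, chrom)
        size = grid.chrom_sizes[chrom]
        s = group["start"].to_numpy(dtype=np.int64)
        e = group["end"].to_numpy(dtype=np.int64)
        if (s < 0).any() or (e > size).any():
            raise DataError(f"target outside bounds of {chrom}")
        k0 = s // w
        k1 = (e - 1) // w
        full = cum_bases[k1 + 1] - cum_bases[k0]
        # trim the parts of the boundary windows that lie outside the target
        left_trim = np.where(mask[k0], s - k0 * w, 0)
        win_end = np.minimum((k1 + 1) * w, size)
        right_trim = np.where(mask[k1], win_end - e, 0)
        total += int((full - left_trim - right_trim).sum())
    return total


def coverage_ratio(
    covered: CoveredWindowSet,
    targets: pd.DataFrame,
    name: str = "target",
) -> CoverageRatio:
    """Base-resolution coverage ratio of a target interval set.

    Overlapping target intervals are merged first, so every base is
    counted once even when features of the same type overlap.
    """
    if len(targets) == 0:
        raise DataError(f"coverage ratio undefined for empty target {name!r}")
    merged = merge_intervals(targets)
    total = int((merged["end"] - merged["start"]).sum())
    return CoverageRatio(name, _covered_bases_in(covered, merged), total)


def element_capture(
    covered: CoveredWindowSet, elements: pd.DataFrame
) -> tuple[int, float]:
    """How many elements overlap at least one covered window by >= 1 bp.

    Returns ``(captured_count, fraction)``; with an empty element table the
    fraction is NaN (reported as not applicable).
    """
    if len(elements) == 0:
        return 0, float("nan")
    grid = covered.grid
    w = grid.width
    captured = 0
    for chrom, group in elements.groupby("chrom", sort=False):
        if chrom not in grid.chrom_sizes:
            raise DataError(f"element on unknown chromosome {chrom}")
        _, _, cum_mask = _covered_prefixes(covered, chrom)
        s = group["start"].to_numpy(dtype=np.int64)
        e = group["end"].to_numpy(dtype=np.int64)
        k0 = s // w
        k1 = np.minimum((e - 1) // w, grid.n_windows(chrom) - 1)
        captured += int(((cum_mask[k1 + 1] - cum_mask[k0]) > 0).sum())
    return captured, captured / len(elements)


def chromosome_coverage_table(covered: CoveredWindowSet) -> pd.DataFrame:
    """Per-chromosome and genome-wide base-resolution coverage ratios."""
    grid = covered.grid
    rows = []
    for chrom in grid.chroms:
        target = pd.DataFrame(
            {"chrom": [chrom], "start": [0], "end": [grid.chrom_sizes[chrom]]}
        )
        r = coverage_ratio(covered, target, name=chrom)
        rows.append((chrom, r.covered_bases, r.total_bases, r.ratio))
    df = pd.DataFrame(rows, columns=["target", "covered_bases", "total_bases", "ratio"])
    genome = pd.DataFrame(
        [
            (
                "genome",
                df["covered_bases"].sum(),
                df["total_bases"].sum(),
                df["covered_bases"].sum() / df["total_bases"].sum(),
            )
        ],
        columns=df.columns,
    )
    return pd.concat([df, genome], ignore_index=True)


def gene_part_coverage_table(
    covered: CoveredWindowSet,
    gene_models,
    promoters: pd.DataFrame | None = None,
    tts_regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Coverage ratio of the genome-wide union of each gene-part type.

    Bases belonging to the same part type of multiple genes are counted
    once (the unions are merged before measuring).
    """
    by_part: dict[str, list[tuple[str, int, int]]] = {}
    for g in gene_models:
        for label, s, e in g.parts:
            by_part.setdefault(label, []).append((g.chrom, s, e))
    rows = []
    frames = {
        label: pd.DataFrame(iv, columns=["chrom", "start", "end"])
        for label, iv in by_part.items()
    }
    if promoters is not None and len(promoters):
        frames["promoter"] = promoters[["chrom", "start", "end"]]
    if tts_regions is not None and len(tts_regions):
        frames["tts"] = tts_regions[["chrom", "start", "end"]]
    for label, frame in frames.items():
        r = coverage_ratio(covered, frame, name=label)
        rows.append((label, r.covered_bases, r.total_bases, r.ratio))
    return pd.DataFrame(rows, columns=["target", "covered_bases", "total_bases", "ratio"])


def classify_cpg_density(
    grid: WindowGrid, cpg_positions: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Per-window CpG-density class: low (0), moderate (1-5), high (>= 6).

    Counts the C position of each CpG falling in the window; the integer
    class bounds are interpreted per ``grid.width`` bases (the canonical
    width is 100 bp, matching the published <1 / 1-5 / >5 per-100-bp
    stratification for integer counts).
    """
    counts = np.zeros(grid.total_windows, dtype=np.int64)
    for chrom in grid.chroms:
        pos = np.asarray(cpg_positions.get(chrom, ()), dtype=np.int64)
        if len(pos) == 0:
            continue
        idx = pos // grid.width
        counts[grid.offset(chrom) : grid.offset(chrom) + grid.n_windows(chrom)] = (
            np.bincount(idx, minlength=grid.n_windows(chrom))
        )
    classes = np.full(grid.total_windows, "moderate", dtype=object)
    classes[counts == 0] = "low"
    classes[counts >= 6] = "high"
    return classes


def cpg_density_strata(
    grid: WindowGrid,
    cpg_positions: Mapping[str, np.ndarray],
    covered: CoveredWindowSet,
    rpkm: RpkmTrack,
) -> pd.DataFrame:
    """Coverage ratio and mean 5hmC density per CpG-density class.

    Density is the mean RPKM (counts per kilobase per million reads) over
    the *covered* windows of the class; a class with no covered window
    reports NaN.
    """
    classes = classify_cpg_density(grid, cpg_positions)
    rows = []
    for cls in CPG_CLASSES:
        sel = classes == cls
        n = int(sel.sum())
        n_cov = int((sel & covered.mask).sum())
        mean_rpkm = (
            float(rpkm.values[sel & covered.mask].mean()) if n_cov else float("nan")
        )
        rows.append((cls, n, n_cov, n_cov / n if n else float("nan"), mean_rpkm))
    df = pd.DataFrame(
        rows,
        columns=["cpg_class", "n_windows", "n_covered", "covered_ratio", "mean_rpkm"],
    )
    assert df["n_windows"].sum() == grid.total_windows
    return df


def _interval_mean_rpkm(rpkm: RpkmTrack, chrom: str, start: int, end: int) -> float:
    """Base-weighted mean RPKM over a genomic interval (NaN if empty)."""
    grid = rpkm.grid
    size = grid.chrom_sizes[chrom]
    start, end = max(0, start), min(end, size)
    if end <= start:
        return float("nan")
    w = grid.width
    k0, k1 = start // w, (end - 1) // w
    o = grid.offset(chrom)
    vals = rpkm.values[o + k0 : o + k1 + 1]
    win_starts = np.arange(k0, k1 + 1, dtype=np.int64) * w
    win_ends = np.minimum(win_starts + w, size)
    overlap = np.minimum(win_ends, end) - np.maximum(win_starts, start)
    return float((vals * overlap).sum() / overlap.sum())


def promoter_rpkm_summary(
    rpkm: RpkmTrack,
    covered: CoveredWindowSet,
    promoters: pd.DataFrame,
) -> tuple[int, float, float]:
    """(covered promoter count, fraction, mean RPKM over covered promoters).

    A promoter is covered iff it overlaps >= 1 covered window; each covered
    promoter contributes its base-weighted mean window RPKM, and the
    summary value is the mean over covered promoters (NaN if none).
    """
    if len(promoters) == 0:
        return 0, float("nan"), float("nan")
    grid = covered.grid
    w = grid.width
    means = []
    n_covered = 0
    for chrom, group in promoters.groupby("chrom", sort=False):
        _, _, cum_mask = _covered_prefixes(covered, chrom)
        for row in group.itertuples():
            k0 = row.start // w
            k1 = min((row.end - 1) // w, grid.n_windows(chrom) - 1)
            if cum_mask[k1 + 1] - cum_mask[k0] > 0:
                n_covered += 1
                means.append(_interval_mean_rpkm(rpkm, chrom, row.start, row.end))
    mean_rpkm = float(np.mean(means)) if means else float("nan")
    return n_covered, n_covered / len(promoters), mean_rpkm


def metagene_profile(
    rpkm: RpkmTrack,
    gene_models,
    gene_sets: Mapping[str, Iterable[str]] | None = None,
    window: tuple[int, int] = (-2500, 500),
    bin_size: int = 500,
) -> pd.DataFrame:
    """Strand-aware mean-RPKM bins around the TSS, averaged per gene set.

    The default window spans TSS-2500 .. TSS+500 split into six 500-bp
    bins, ordered 5'->3' along transcription (bin 1 is the most upstream).
    On the minus strand the bins mirror: transcript offset ``x`` maps to
    genomic position ``tss - x``. Bins falling entirely outside the
    chromosome are NaN and are excluded from the set mean.

    Returns a tidy frame: set, bin (1-based), offset_start, offset_end,
    mean_rpkm, n_genes.
    """
    span = window[1] - window[0]
    if span % bin_size != 0:
        raise ConfigError(
            f"window span {span} is not divisible by bin size {bin_size}"
        )
    n_bins = span // bin_size
    if gene_sets is None:
        gene_sets = {"all": [g.gene_id for g in gene_models]}
    by_id = {g.gene_id: g for g in gene_models}
    per_gene: dict[str, np.ndarray] = {}
    for gid, g in by_id.items():
        vals = np.empty(n_bins)
        for b in range(n_bins):
            off0 = window[0] + b * bin_size
            off1 = off0 + bin_size
            if g.strand == "+":
                s, e = g.tss + off0, g.tss + off1
            else:
                # transcript offsets [off0, off1) map to genomic (tss-off1, tss-off0]
                s, e = g.tss - off1 + 1, g.tss - off0 + 1
            vals[b] = _interval_mean_rpkm(rpkm, g.chrom, s, e)
        per_gene[gid] = vals
    rows = []
    for set_name, ids in gene_sets.items():
        members = [per_gene[i] for i in ids if i in per_gene]
        for b in range(n_bins):
            vals = np.array([m[b] for m in members]) if members else np.empty(0)
            ok = vals[~np.isnan(vals)] if len(vals) else vals
            rows.append(
                (
                    set_name,
                    b + 1,
                    window[0] + b * bin_size,
                    window[0] + (b + 1) * bin_size,
                    float(ok.mean()) if len(ok) else float("nan"),
                    len(ok),
                )
            )
    return pd.DataFrame(
        rows, columns=["set", "bin", "offset_start", "offset_end", "mean_rpkm", "n_genes"]
    )
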