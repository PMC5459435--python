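"""Genomic annotation of DhMRs: promoters, feature assignment, gene mapping.

All interval algebra is 0-based half-open. Feature assignment is a total
function: every DhMR receives exactly one primary feature, chosen from all
>= 1 bp overlaps by the precedence

    promoter > 5'UTR > exon > 3'UTR > TTS > intron > intergenic

(regulatory and transcript-end features outrank the bulk intron class;
a window touching nothing gene-linked is intergenic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError

__all__ = [
    "FEATURE_PRECEDENCE",
    "AnnotationIndex",
    "build_promoters",
    "build_tts_regions",
    "assign_primary_feature",
    "assign_repeat_classes",
    "dhmrs_to_genes",
    "flag_imprinted_promoters",
]

FEATURE_PRECEDENCE = (
    "promoter",
    "five_prime_utr",
    "exon",
    "three_prime_utr",
    "tts",
    "intron",
)


def build_promoters(
    gene_models,
    upstream: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Candidate promoters: the ``upstream`` bp 5' of each TSS, strand-aware.

    Plus strand: [TSS-upstream, TSS); minus strand: [TSS+1, TSS+1+upstream)
    in genomic coordinates. Clipped at chromosome bounds.
    """
    rows = []
    for g in gene_models:
        if g.strand not in ("+", "-"):
            raise DataError(f"gene {g.gene_id} has no usable strand: {g.strand!r}")
        if g.strand == "+":
            start, end = g.start - upstream, g.start
        else:
            start, end = g.end, g.end + upstream
        start = max(0, start)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[g.chrom])
        if end > start:
            rows.append((g.gene_id, g.chrom, start, end, g.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def build_tts_regions(
    gene_models,
    width: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Transcription-termination regions: ``width`` bp downstream of gene end."""
    rows = []
    for g in gene_models:
        if g.strand == "+":
            start, end = g.end, g.end + width
        else:
            start, end = g.start - width, g.start
        start = max(0, start)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[g.chrom])
        if end > start:
            rows.append((g.gene_id, g.chrom, start, end, g.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


@dataclass
class AnnotationIndex:
    """Interval trees over gene parts, promoters and TTS regions."""

    trees: dict[str, IntervalTree]  # keyed by chromosome

    @classmethod
    def build(
        cls,
        gene_models,
        promoters: pd.DataFrame,
        tts_regions: pd.DataFrame,
    ) -> "AnnotationIndex":
        trees: dict[str, IntervalTree] = {}

        def add(chrom: str, start: int, end: int, feature: str, gene_id: str) -> None:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, (feature, gene_id))

        for g in gene_models:
            for label, s, e in g.parts:
                add(g.chrom, s, e, label, g.gene_id)
        for row in promoters.itertuples():
            add(row.chrom, row.start, row.end, "promoter", row.gene_id)
        for row in tts_regions.itertuples():
            add(row.chrom, row.start, row.end, "tts", row.gene_id)
        return cls(trees)

    def query(self, chrom: str, start: int, end: int) -> list[tuple[str, str]]:
        """All (feature, gene_id) pairs overlapping [start, end) by >= 1 bp."""
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def assign_primary_feature(dhmrs: pd.DataFrame, index: AnnotationIndex) -> pd.DataFrame:
    """Attach primary_feature and the touched gene ids to a DhMR table."""
    primaries, gene_lists = [], []
    for row in dhmrs.itertuples():
        hits = index.query(row.chrom, row.start, row.end)
        features = {f for f, _ in hits}
        primary = "intergenic"
        for feat in FEATURE_PRECEDENCE:
            if feat in features:
                primary = feat
                break
        primaries.append(primary)
        gene_lists.append(sorted({g for _, g in hits}))
    out = dhmrs.copy()
    out["primary_feature"] = primaries
    out["gene_ids"] = [",".join(g) for g in gene_lists]
    return out


def assign_repeat_classes(dhmrs: pd.DataFrame, repeats: pd.DataFrame) -> pd.DataFrame:
    """Many-to-many attribution of DhMRs to repeat classes (>= 1 bp overlap)."""
    trees: dict[str, IntervalTree] = {}
    for row in repeats.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row.repeat_class
        )
    classes = []
    for row in dhmrs.itertuples():
        tree = trees.get(row.chrom)
        hits = sorted({iv.data for iv in tree.overlap(row.start, row.end)}) if tree else []
        classes.append(",".join(hits))
    out = dhmrs.copy()
    out["repeat_classes"] = classes
    return out


def dhmrs_to_genes(
    dhmrs: pd.DataFrame,
    gene_models,
    promoters: pd.DataFrame,
) -> pd.DataFrame:
    """Gene-level table: which genes are touched by hyper/hypo DhMRs.

    A gene is affected by a direction iff at least one DhMR of that
    direction overlaps its promoter or its gene body; a gene can appear in
    both direction sets.
    """
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    for row in promoters.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row.gene_id
        )
    hyper: set[str] = set()
    hypo: set[str] = set()
    for row in dhmrs.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        genes = {iv.data for iv in tree.overlap(row.start, row.end)}
        if row.direction == "hyper":
            hyper |= genes
        else:
            hypo |= genes
    all_ids = sorted(hyper | hypo)
    return pd.DataFrame(
        {
            "gene_id": all_ids,
            "hyper": [g in hyper for g in all_ids],
            "hypo": [g in hypo for g in all_ids],
        }
    )


def affected_gene_summary(gene_table: pd.DataFrame) -> dict[str, int]:
    """Hyper/hypo/union/intersection cardinalities of the affected-gene sets."""
    n_hyper = int(gene_table["hyper"].sum())
    n_hypo = int(gene_table["hypo"].sum())
    union = len(gene_table)
    return {
        "hyper_genes": n_hyper,
        "hypo_genes": n_hypo,
        "affected_genes": union,
        "both_directions": n_hyper + n_hypo - union,
    }


def flag_imprinted_promoters(
    dhmrs: pd.DataFrame,
    promoters: pd.DataFrame,
    imprinted: Mapping[str, str],
    direction: str | None = "hyper",
) -> pd.DataFrame:
    """Imprinted genes whose promoter overlaps a DhMR.

    ``imprinted`` maps gene id -> parent-of-origin label (maternal /
    paternal), carried through to the output. ``direction`` restricts to
    hyper or hypo DhMRs (None = any). Imprinted ids absent from the
    promoter table are skipped with a warning.
    """
    known = set(promoters["gene_id"])
    unknown = set(imprinted) - known
    if unknown:
        warnings.warn(
            f"{len(unknown)} imprinted gene id(s) not in the promoter table; skipped"
        )
    sel = dhmrs if direction is None else dhmrs[dhmrs["direction"] == direction]
    trees: dict[str, IntervalTree] = {}
    for row in sel.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, None)
    rows = []
    for row in promoters.itertuples():
        if row.gene_id not in imprinted:
            continue
        tree = trees.get(row.chrom)
        if tree is not None and tree.overlap(row.start, row.end):
            rows.append((row.gene_id, imprinted[row.gene_id]))
    return pd.DataFrame(rows, columns=["gene_id", "parent_of_origin"])
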