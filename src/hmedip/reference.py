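"""Reference count arithmetic of the pooled-sperm 5hmC study, recomputed live.

The motivating hMeDIP-seq analysis of occupational-BPA-exposed human sperm
published only summary counts (captured CpG islands, covered promoters,
DhMR and affected-gene tallies, histone-mark overlaps) — no raw data. Those
printed counts are therefore *inputs*: this module lays out synthetic
genomes/ID sets with exactly the published cardinalities and pushes them
through the pipeline's real operations (element capture, promoter summary,
gene mapping, overlap report), so the published percentages come out of the
same code paths users run, not out of a lookup table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import affected_gene_summary, build_promoters, dhmrs_to_genes
from .coverage import element_capture, promoter_rpkm_summary
from .enrichment import overlap_report
from .simulate import GeneModel
from .windows import CoveredWindowSet, RpkmTrack, WindowGrid

__all__ = ["REFERENCE_COUNTS", "compute_reference_ratios"]

#: published integer counts this module re-derives percentages from
REFERENCE_COUNTS = {
    "cgi_total": 28_691,
    "cgi_captured_exposed": 20_078,
    "cgi_captured_control": 16_319,
    "promoter_total": 29_310,
    "promoters_covered_exposed": 10_993,
    "promoters_covered_control": 10_538,
    "dhmr_hyper": 8_670,
    "dhmr_hypo": 940,
    "genes_hyper": 1_870,
    "genes_hypo": 274,
    "genes_affected": 2_008,
    "expressed_total": 6_709,
    "expressed_affected": 762,
    "h3k4me2_total": 5_455,
    "h3k4me2_affected": 573,
    "h3k4me3_total": 9_073,
    "h3k4me3_affected": 895,
    "h3k27me3_total": 3_911,
    "h3k27me3_affected": 474,
    "bivalent_total": 2_478,
    "bivalent_affected": 306,
}


def _capture_fraction(n_total: int, n_captured: int, width: int = 100) -> float:
    """Element-capture fraction for ``n_captured`` of ``n_total`` elements.

    One element per grid window; the first ``n_captured`` windows covered.
    """
    grid = WindowGrid({"ref": n_total * width}, width)
    mask = np.zeros(grid.total_windows, dtype=bool)
    mask[:n_captured] = True
    covered = CoveredWindowSet(grid, mask)
    starts = np.arange(n_total, dtype=np.int64) * width
    elements = pd.DataFrame({"chrom": "ref", "start": starts, "end": starts + width})
    count, fraction = element_capture(covered, elements)
    assert count == n_captured
    return fraction


def _promoter_fraction(n_total: int, n_covered: int, width: int = 100) -> float:
    """Covered-promoter fraction through the promoter summary operation."""
    grid = WindowGrid({"ref": n_total * width}, width)
    mask = np.zeros(grid.total_windows, dtype=bool)
    mask[:n_covered] = True
    covered = CoveredWindowSet(grid, mask)
    rpkm = RpkmTrack(grid, np.ones(grid.total_windows), library_total=1_000_000)
    starts = np.arange(n_total, dtype=np.int64) * width
    promoters = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_total)],
            "chrom": "ref",
            "start": starts,
            "end": starts + width,
            "strand": "+",
        }
    )
    count, fraction, _ = promoter_rpkm_summary(rpkm, covered, promoters)
    assert count == n_covered
    return fraction


def _affected_gene_arithmetic() -> dict[str, int]:
    """Union/intersection of hyper- and hypo-affected genes via gene mapping.

    Lays out one gene per 10 kb and plants one window-sized DhMR inside the
    body of each gene in its direction set(s); the published union of 2,008
    forces an intersection of 136 genes hit by both directions.
    """
    c = REFERENCE_COUNTS
    n_union = c["genes_affected"]
    n_both = c["genes_hyper"] + c["genes_hypo"] - n_union
    spacing, body = 10_000, 3_000
    genes = []
    dhmr_rows = []
    for i in range(n_union):
        start = i * spacing + 4_000
        genes.append(
            GeneModel(f"g{i:05d}", "ref", "+", start, start + body, parts=[])
        )
        hyper = i < c["genes_hyper"]
        hypo = i >= c["genes_hyper"] - n_both
        if hyper:
            dhmr_rows.append(("ref", start + 100, start + 200, "hyper"))
        if hypo:
            dhmr_rows.append(("ref", start + 300, start + 400, "hypo"))
    dhmrs = pd.DataFrame(dhmr_rows, columns=["chrom", "start", "end", "direction"])
    promoters = build_promoters(genes, upstream=2000)
    table = dhmrs_to_genes(dhmrs, genes, promoters)
    return affected_gene_summary(table)


def _set_overlap_report() -> pd.DataFrame:
    """Published gene-set overlaps through the enrichment report.

    Affected genes and each catalogue are synthetic ID sets with exactly
    the published cardinalities and intersection sizes; the universe is
    the published promoter-catalogue size.
    """
    c = REFERENCE_COUNTS
    affected = [f"g{i:05d}" for i in range(c["genes_affected"])]

    def id_set(k_in_affected: int, total: int) -> set[str]:
        ids = set(affected[:k_in_affected])
        ids |= {f"x{len(ids)}_{j}" for j in range(total - k_in_affected)}
        return ids

    sets = {
        "expressed": id_set(c["expressed_affected"], c["expressed_total"]),
        "h3k4me2": id_set(c["h3k4me2_affected"], c["h3k4me2_total"]),
        "h3k4me3": id_set(c["h3k4me3_affected"], c["h3k4me3_total"]),
        "h3k27me3": id_set(c["h3k27me3_affected"], c["h3k27me3_total"]),
        "bivalent": id_set(c["bivalent_affected"], c["bivalent_total"]),
        "all_genes": id_set(c["genes_affected"], c["promoter_total"]),
    }
    return overlap_report(affected, sets, universe=c["promoter_total"])


def compute_reference_ratios() -> dict[str, float]:
    """All published percentages/counts, recomputed through the pipeline ops."""
    c = REFERENCE_COUNTS
    report = _set_overlap_report().set_index("set")
    gene_arith = _affected_gene_arithmetic()
    return {
        "cgi_capture_exposed_pct": 100 * _capture_fraction(
            c["cgi_total"], c["cgi_captured_exposed"]
        ),
        "cgi_capture_control_pct": 100 * _capture_fraction(
            c["cgi_total"], c["cgi_captured_control"]
        ),
        "promoter_covered_exposed_pct": 100 * _promoter_fraction(
            c["promoter_total"], c["promoters_covered_exposed"]
        ),
        "promoter_covered_control_pct": 100 * _promoter_fraction(
            c["promoter_total"], c["promoters_covered_control"]
        ),
        "dhmr_total": c["dhmr_hyper"] + c["dhmr_hypo"],
        "affected_genes_union": gene_arith["affected_genes"],
        "affected_genes_both_directions": gene_arith["both_directions"],
        "genes_affected_pct": 100 * report.loc["all_genes", "fraction"],
        "expressed_affected_pct": 100 * report.loc["expressed", "fraction"],
        "h3k4me2_dhmr_pct": 100 * report.loc["h3k4me2", "fraction"],
        "h3k4me3_dhmr_pct": 100 * report.loc["h3k4me3", "fraction"],
        "h3k27me3_dhmr_pct": 100 * report.loc["h3k27me3", "fraction"],
        "bivalent_dhmr_pct": 100 * report.loc["bivalent", "fraction"],
    }
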