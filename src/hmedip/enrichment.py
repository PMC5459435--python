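"""Gene-set overlap and enrichment statistics.

Overlap fractions are exact integer ratios k/K; enrichment significance is
the upper-tail hypergeometric test against a stated gene universe, with
Benjamini-Hochberg adjustment across the sets of one report. A two-sided
Fisher exact test is provided for 2x2 comparisons between classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "GeneSet",
    "hypergeom_test",
    "fisher_exact",
    "bh_fdr",
    "overlap_report",
]


@dataclass(frozen=True)
class GeneSet:
    """Named gene-id collection with an optional role tag.

    Roles mirror the catalogues this analysis consumes: expressed
    (RPKM > 1), highly expressed (RPKM > 50), repressed (testis RPKM > 25
    and sperm RPKM < 1), H3K4me2 / H3K4me3 / H3K27me3-bound, bivalent
    (K4me3 AND K27me3) and imprinted.
    """

    name: str
    ids: frozenset = field(default_factory=frozenset)
    role: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", frozenset(self.ids))

    def __len__(self) -> int:
        return len(self.ids)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail enrichment p-value: P(X >= k), X ~ Hypergeom(N, K, n).

    ``N`` genes in the universe, ``K`` of them in the set, ``n`` drawn
    (affected), ``k`` of the drawn in the set.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise DataError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one. An all-zero table and
    any table with a zero margin give p = 1.
    """
    for x in (a, b, c, d):
        if not float(x).is_integer() or x < 0:
            raise DataError(f"table entries must be non-negative integers, got {x!r}")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_report(
    affected_genes: Iterable[str],
    gene_sets: Iterable[GeneSet] | Mapping[str, Iterable[str]],
    universe: int | Iterable[str],
) -> pd.DataFrame:
    """Overlap and enrichment of an affected-gene list against gene sets.

    For each set reports k = |affected ∩ set|, K = |set|, n = |affected|,
    N = universe size, the overlap fraction k/K, the upper-tail
    hypergeometric p and the BH q across the sets of this report. The
    universe may be a plain size or an explicit id collection; ids outside
    an explicit universe trigger a warning and are dropped from k/K/n.
    """
    affected = set(affected_genes)
    if isinstance(gene_sets, Mapping):
        gene_sets = [GeneSet(name, frozenset(ids)) for name, ids in gene_sets.items()]
    else:
        gene_sets = list(gene_sets)

    if isinstance(universe, int):
        N = universe
        universe_ids = None
    else:
        universe_ids = set(universe)
        N = len(universe_ids)
        out = affected - universe_ids
        if out:
            warnings.warn(f"{len(out)} affected gene id(s) outside the universe; dropped")
            affected &= universe_ids
    n = len(affected)
    if N < n:
        raise DataError(f"universe size {N} smaller than affected-set size {n}")

    rows = []
    for gs in gene_sets:
        ids = set(gs.ids)
        if universe_ids is not None:
            out = ids - universe_ids
            if out:
                warnings.warn(
                    f"set {gs.name!r}: {len(out)} id(s) outside the universe; dropped"
                )
                ids &= universe_ids
        K = len(ids)
        if K > N:
            raise DataError(f"set {gs.name!r} larger than the universe")
        k = len(affected & ids)
        rows.append(
            (
                gs.name,
                k,
                K,
                n,
                N,
                k / K if K else float("nan"),
                hypergeom_test(k, K, n, N),
            )
        )
    df = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "fraction", "p_value"])
    df["q_value"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    return df
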