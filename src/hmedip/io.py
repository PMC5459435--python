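"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: BED and all in-memory intervals are 0-based half-open; GFF3 is
1-based closed and converted at the boundary. chrom.sizes is a two-column
TSV (name, length). Window tracks are written bedGraph-style
(chrom, start, end, value; no header).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

BED6_NAMES = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    if df["size"].isna().any() or (df["size"] <= 0).any():
        raise DataError(f"invalid chromosome sizes in {path}")
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    """Read a headerless BED3..BED6 file, keeping only the named columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = names or BED6_NAMES[: df.shape[1]]
    if df.shape[1] < len(names):
        names = names[: df.shape[1]]
    df = df.iloc[:, : len(names)]
    df.columns = names
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            raise DataError(f"empty or inverted interval in {path}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_NAMES if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; a second tab-separated column, if present, is ignored."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            ids.add(line.split("\t")[0])
    return ids


def read_labeled_gene_list(path: str | Path) -> dict[str, str]:
    """Two-column gene list: id <tab> label (e.g. parent of origin)."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = parts[1] if len(parts) > 1 else ""
    return out


def write_gene_models_gff(gene_models, path: str | Path) -> None:
    """Write canonical gene models as GFF3 (gene + part features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_models:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for label, s, e in g.parts:
                fh.write(
                    f"{g.chrom}\tsim\t{label}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )


def read_gene_models_gff(path: str | Path):
    """Read gene models written by :func:`write_gene_models_gff`.

    Multi-feature genes are reassembled from Parent attributes; parts are
    returned in ascending genomic order. If a gene id appears more than
    once, only the longest record is kept (one canonical model per gene).
    """
    import gffutils

    from .simulate import GeneModel

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes["ID"][0]
        parts = []
        for child in db.children(feat, order_by="start"):
            parts.append((child.featuretype, child.start - 1, child.end))
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,
                end=feat.end,
                parts=parts,
            )
        )
    best: dict[str, object] = {}
    for g in genes:
        kept = best.get(g.gene_id)
        if kept is None or (g.end - g.start) > (kept.end - kept.start):
            best[g.gene_id] = g
    return sorted(best.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def write_track(grid, values: np.ndarray, path: str | Path) -> None:
    """bedGraph-style per-window values."""
    frame = grid.to_frame()
    frame["value"] = values
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_track(grid, path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    if len(df) != grid.total_windows:
        raise DataError(
            f"track {path} has {len(df)} rows, grid expects {grid.total_windows}"
        )
    return df["value"].to_numpy()
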