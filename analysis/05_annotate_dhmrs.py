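#!/usr/bin/env python
"""Annotate the called DhMRs against the gene models and repeats.

Assigns each DhMR a primary genomic feature (promoter > 5'UTR > exon >
3'UTR > TTS > intron > intergenic), maps DhMRs to affected genes by
direction, attributes repeat classes, and flags imprinted-gene promoters
overlapped by hyper-hMRs.
"""

from pathlib import Path

import pandas as pd

from hmedip import annotate
from hmedip.simulate import load_fixtures

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    genome, _, _ = load_fixtures(RESULTS / "fixtures")
    dhmrs = pd.read_csv(RESULTS / "dhmr" / "dhmrs.tsv", sep="\t")
    out = RESULTS / "annotation"
    out.mkdir(parents=True, exist_ok=True)

    promoters = annotate.build_promoters(genome.gene_models, 2000, genome.chrom_sizes)
    tts = annotate.build_tts_regions(genome.gene_models, 1000, genome.chrom_sizes)
    index = annotate.AnnotationIndex.build(genome.gene_models, promoters, tts)

    annotated = annotate.assign_primary_feature(dhmrs, index)
    annotated = annotate.assign_repeat_classes(annotated, genome.repeats)
    annotated.to_csv(out / "dhmrs_annotated.tsv", sep="\t", index=False)
    dist = annotated["primary_feature"].value_counts()
    print("primary-feature distribution:",
          ", ".join(f"{k} {v}" for k, v in dist.items()))

    gene_table = annotate.dhmrs_to_genes(dhmrs, genome.gene_models, promoters)
    gene_table.to_csv(out / "dhmr_genes.tsv", sep="\t", index=False)
    summary = annotate.affected_gene_summary(gene_table)
    print(f"affected genes: {summary['affected_genes']} "
          f"({summary['hyper_genes']} by hyper, {summary['hypo_genes']} by hypo, "
          f"{summary['both_directions']} by both)")

    flags = annotate.flag_imprinted_promoters(dhmrs, promoters, genome.imprinted_origin)
    flags.to_csv(out / "imprinted_flags.tsv", sep="\t", index=False)
    print(f"imprinted promoters with hyper-hMRs: {len(flags)} "
          f"of {len(genome.imprinted_origin)} imprinted genes")


if __name__ == "__main__":
    main()
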