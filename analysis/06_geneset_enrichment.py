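#!/usr/bin/env python
"""Gene-set overlap and enrichment of the DhMR-affected genes.

Hypergeometric enrichment of the affected-gene list against the
expression, histone-mark and imprinted catalogues, with BH FDR across the
report; prints the overlap fractions in the style of the published
count-ratio statistics.
"""

from pathlib import Path

import pandas as pd

from hmedip.enrichment import overlap_report
from hmedip.simulate import load_fixtures

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    genome, _, _ = load_fixtures(RESULTS / "fixtures")
    gene_table = pd.read_csv(RESULTS / "annotation" / "dhmr_genes.tsv", sep="\t")
    affected = gene_table["gene_id"].tolist()
    out = RESULTS / "enrichment"
    out.mkdir(parents=True, exist_ok=True)

    report = overlap_report(affected, genome.gene_sets(), universe=set(genome.gene_ids))
    report.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    for row in report.itertuples():
        frac = f"{row.fraction:.1%}" if row.K else "n/a"
        print(f"{row.set:>16}: {row.k}/{row.K} affected ({frac}); "
              f"p = {row.p_value:.3g}, q = {row.q_value:.3g}")
    print(f"enrichment report written to {out}")


if __name__ == "__main__":
    main()
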