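#!/usr/bin/env python
"""Simulate the two-condition hMeDIP-seq study and write the fixture bundle.

Builds the toy genome (gene models, CpG landscape with islands, repeat
classes, expression/histone/imprinted gene sets), plants hyper- and
hypo-hydroxymethylated 100-bp windows at a 4-fold change, draws 51-bp reads
for the control and exposed libraries, and serialises everything under
results/fixtures/ together with the ground-truth table.
"""

import argparse
from pathlib import Path

from hmedip.simulate import (
    SimulationConfig,
    build_toy_genome,
    plant_dhmr_signals,
    simulate_reads,
    write_fixtures,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--depth", type=float, default=20.0)
    args = parser.parse_args()

    config = SimulationConfig(seed=args.seed, depth_per_window=args.depth)
    genome = build_toy_genome(config)
    signal = plant_dhmr_signals(genome, config)
    reads = {
        cond: simulate_reads(genome, signal, config, cond)
        for cond in ("control", "exposed")
    }
    out = RESULTS / "fixtures"
    paths = write_fixtures(genome, signal, reads, out)
    print(f"toy genome: {sum(genome.chrom_sizes.values()):,} bp, "
          f"{len(genome.gene_models)} genes, "
          f"{sum(len(v) for v in genome.cpg_positions.values()):,} CpGs")
    print(f"planted signal: {int((signal.records['direction'] == 'hyper').sum())} hyper, "
          f"{int((signal.records['direction'] == 'hypo').sum())} hypo windows "
          f"at fold {config.fold_change}")
    print(f"reads: control {len(reads['control']):,}, exposed {len(reads['exposed']):,} "
          f"(ratio {len(reads['exposed']) / len(reads['control']):.3f})")
    print(f"wrote {len(paths)} files to {out}")


if __name__ == "__main__":
    main()
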