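#!/usr/bin/env python
"""Stitch H3K27ac peaks into candidate regions, rank by signal, call
super-enhancers above the rank-curve inflection and compare the two cells."""

import argparse
from pathlib import Path

import pandas as pd

from cistro.pipeline import (
    RunConfig,
    load_inputs,
    stage_inputs,
    stage_superenhancers,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/superenhancers"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = RunConfig(data_dir=str(args.data), seed=args.seed)
    inputs = load_inputs(args.data)
    ctx: dict = {}
    stage_inputs(cfg, inputs, ctx, args.out)
    stage_superenhancers(cfg, inputs, ctx, args.out)

    comparison = pd.read_csv(args.out / "se_comparison.tsv", sep="\t")
    print(f"super-enhancer calls -> {args.out} "
          f"(stitch {cfg.stitch_bp / 1000:g} kb, TSS exclusion "
          f"{cfg.tss_exclusion_bp / 1000:g} kb)")
    for row in comparison.itertuples(index=False):
        print(f"  {row.quantity}: {row.count}")
    for cell in (cfg.cell_a, cfg.cell_b):
        stitched = pd.read_csv(args.out / f"stitched_{cell}.tsv", sep="\t")
        supers = stitched[stitched["is_super"]]
        print(f"  {cell}: {len(stitched)} stitched regions, "
              f"{len(supers)} super (median constituents "
              f"{supers['n_constituents'].median():g})")


if __name__ == "__main__":
    main()
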