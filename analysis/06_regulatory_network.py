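#!/usr/bin/env python
"""Scan PWMs over cell-specific active promoters/enhancers, keep enriched
motifs, build TF-target networks and score TF-TF cooperation by Jaccard
index."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cistro.pipeline import (
    RunConfig,
    load_inputs,
    stage_enhancers,
    stage_inputs,
    stage_network,
    stage_promoters,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/network"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = RunConfig(data_dir=str(args.data), seed=args.seed)
    inputs = load_inputs(args.data)
    ctx: dict = {}
    for stage in (stage_inputs, stage_promoters, stage_enhancers, stage_network):
        stage(cfg, inputs, ctx, args.out)

    edges = pd.read_csv(args.out / "edges.tsv", sep="\t")
    enrich = pd.read_csv(args.out / "motif_enrichment.tsv", sep="\t")
    hubs = pd.read_csv(args.out / "hubs.tsv", sep="\t")
    sig = enrich[enrich["p"] < cfg.motif_p]
    print(f"regulatory networks -> {args.out}")
    print(f"  {len(sig)} (TF, cell) motif enrichments below p < {cfg.motif_p:g}")
    for cell, sub in edges.groupby("cell"):
        modes = sub["mode"].value_counts().to_dict()
        print(f"  {cell}: {len(sub)} TF->target edges {modes}")
    ji_b = ctx[f"jaccard_{cfg.cell_b}"]
    if len(ji_b):
        off_diag = ji_b.values[~np.eye(len(ji_b), dtype=bool)]
        print(f"  {cfg.cell_b} cooperation: median off-diagonal JI "
              f"{float(np.median(off_diag)):.2f}; "
              f"hubs: {hubs[hubs['cell'] == cfg.cell_b]['tf'].tolist()}")


if __name__ == "__main__":
    main()
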