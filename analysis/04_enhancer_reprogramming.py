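#!/usr/bin/env python
"""Call distal enhancers, classify gained/lost regions between cells and
build the promoter x enhancer x expression synergy table."""

import argparse
from collections import Counter
from pathlib import Path

from cistro.pipeline import (
    RunConfig,
    load_inputs,
    stage_enhancers,
    stage_inputs,
    stage_promoters,
    stage_synergy,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/enhancers"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = RunConfig(data_dir=str(args.data), seed=args.seed)
    inputs = load_inputs(args.data)
    ctx: dict = {}
    for stage in (stage_inputs, stage_promoters, stage_enhancers, stage_synergy):
        stage(cfg, inputs, ctx, args.out)

    status = Counter(c.status for c in ctx["enhancer_calls"])
    print(f"{sum(status.values())} enhancer-union regions -> {args.out}")
    print(f"  gained {status['gained']}, lost {status['lost']}, "
          f"stable {status['stable']} "
          f"(>= {cfg.min_fold:g}-fold, p < {cfg.max_p:g})")
    table = ctx["synergy"]
    for label in ("P-activated & E-gained", "P-activated & E-none",
                  "P-repressed & E-lost"):
        sub = table[table["label"] == label]
        if len(sub):
            print(f"  {label}: n={len(sub)}, mean log2 FC {sub['log2fc'].mean():+.2f}")


if __name__ == "__main__":
    main()
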