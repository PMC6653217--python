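"""Gene-set enrichment and cancer-hallmark change summaries.

Enrichment of a query gene list against named sets is an upper-tail
hypergeometric test per set with Benjamini-Hochberg correction across sets
(kept at FDR <= 0.05) — a generic stand-in for ontology-backed tools, run
against whatever GMT collections are supplied.  Hallmark summaries report,
per hallmark set, the percentage of its genes carrying a promoter-state
transition, a differential enhancer, or differential expression.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Set

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def geneset_enrichment(
    query: Set[str],
    sets: Mapping[str, Set[str]],
    universe: Set[str],
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``query`` in each gene set.

    Sets are intersected with the universe first; the query must be a
    subset of the universe.  Returns one row per set with k (overlap),
    K (set size), n (query size), N (universe size), p, BH-adjusted fdr and
    the kept flag (fdr <= ``max_fdr``), sorted by p.
    """
    if not universe:
        raise ValueError("universe is empty")
    extra = set(query) - set(universe)
    if extra:
        raise ValueError(f"{len(extra)} query genes missing from the universe")
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & set(universe)
        k = len(members & set(query))
        p = float(stats.hypergeom.sf(k - 1, N, len(members), n))
        rows.append(dict(set_name=name, k=k, K=len(members), n=n, N=N, p=p))
    df = pd.DataFrame(rows)
    if len(df):
        _, fdr, _, _ = multipletests(df["p"], method="fdr_bh")
        df["fdr"] = fdr
        df["kept"] = df["fdr"] <= max_fdr
        df = df.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    else:
        df["fdr"] = []
        df["kept"] = []
    return df


def hallmark_percentages(
    hallmark_sets: Mapping[str, Set[str]],
    promoter_changed: Set[str],
    enhancer_changed: Set[str],
    deg_genes: Set[str],
) -> pd.DataFrame:
    """Per-hallmark percentage of member genes changed on each layer.

    "Changed promoter" means any off-diagonal state transition; "changed
    enhancer" means at least one assigned gained/lost enhancer; "changed
    expression" means membership in the DEG list.  Denominator is the
    hallmark set size.
    """
    rows = []
    for name in sorted(hallmark_sets):
        members = set(hallmark_sets[name])
        if not members:
            raise ValueError(f"hallmark set {name!r} is empty")
        size = len(members)
        rows.append(
            dict(
                hallmark=name,
                n_genes=size,
                pct_promoter_changed=100.0 * len(members & set(promoter_changed)) / size,
                pct_enhancer_changed=100.0 * len(members & set(enhancer_changed)) / size,
                pct_expression_changed=100.0 * len(members & set(deg_genes)) / size,
            )
        )
    return pd.DataFrame(rows)
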