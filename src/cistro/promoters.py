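"""Promoter chromatin-state classification and transition accounting.

A promoter is the TSS +/- 2 kb window.  Its state in a cell follows from
which marks are enriched on it:

* Active     — H3K4me3 or H3K27ac, without H3K27me3;
* Repressive — H3K27me3 without either active mark;
* Poised     — an active mark together with H3K27me3 (bivalent);
* None       — no mark enriched.

Enrichment is peak-overlap based: a mark is enriched when its peaks overlap
the window by at least ``min_overlap_bp`` and the normalized tag density
over the window reaches ``min_density``.  The per-mark numeric thresholds
behind the published state calls are not recoverable, so both knobs are
explicit configuration with peak presence (1 bp, density 0) as the default
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import ExpressionRecord, GeneModel, GenomicInterval, Peak
from .simulate import STATES


def define_promoters(
    genes: Sequence[GeneModel],
    halfwidth_bp: int = 2_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, GenomicInterval]:
    """TSS +/- ``halfwidth_bp`` windows, clipped at chromosome edges."""
    if halfwidth_bp <= 0:
        raise ValueError("halfwidth_bp must be positive")
    windows: dict[str, GenomicInterval] = {}
    for g in genes:
        start = max(0, g.tss - halfwidth_bp)
        end = g.tss + halfwidth_bp
        if chrom_sizes is not None and g.chrom in chrom_sizes:
            end = min(end, chrom_sizes[g.chrom])
        windows[g.gene_id] = GenomicInterval(g.chrom, start, end, g.strand)
    return windows


def _peak_tree(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, p
        )
    return trees


def mark_enrichment(
    window: GenomicInterval,
    peaks: Sequence[Peak] | dict[str, IntervalTree],
    min_overlap_bp: int = 1,
    min_density: float = 0.0,
    library_size: float | None = None,
) -> tuple[bool, float]:
    """Whether one mark is enriched on ``window``, plus its density there.

    Density is the window-overlapping share of each peak's tags per kb of
    window, per million library tags when a library size is given.
    """
    trees = peaks if isinstance(peaks, dict) else _peak_tree(peaks)
    overlap_bp = 0
    tags = 0.0
    for iv in trees.get(window.chrom, IntervalTree()).overlap(window.start, window.end):
        peak: Peak = iv.data
        ovl = window.overlap_bp(peak.interval)
        overlap_bp += ovl
        tags += peak.tag_count * ovl / peak.interval.length
    density = tags / (window.length / 1_000.0)
    if library_size:
        density /= library_size / 1e6
    return (overlap_bp >= min_overlap_bp and density >= min_density), density


def classify_state(k4me3: bool, k27ac: bool, k27me3: bool) -> str:
    """Map the three enrichment flags to Active/Repressive/Poised/None."""
    active_mark = k4me3 or k27ac
    if active_mark and not k27me3:
        return "Active"
    if active_mark and k27me3:
        return "Poised"
    if k27me3:
        return "Repressive"
    return "None"


def classify_promoters(
    genes: Sequence[GeneModel],
    peaks_by_mark: Mapping[str, Sequence[Peak]],
    halfwidth_bp: int = 2_000,
    min_overlap_bp: int = 1,
    min_density: float = 0.0,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene state call for one cell, with per-mark flags and densities."""
    windows = define_promoters(genes, halfwidth_bp, chrom_sizes)
    trees = {mark: _peak_tree(pk) for mark, pk in peaks_by_mark.items()}
    rows = []
    for g in genes:
        window = windows[g.gene_id]
        flags: dict[str, bool] = {}
        row: dict[str, object] = {"gene_id": g.gene_id}
        for mark in ("H3K4me3", "H3K27ac", "H3K27me3"):
            flag, density = mark_enrichment(
                window, trees.get(mark, {}), min_overlap_bp, min_density
            )
            flags[mark] = flag
            row[f"{mark}_enriched"] = flag
            row[f"{mark}_density"] = density
        row["state"] = classify_state(
            flags["H3K4me3"], flags["H3K27ac"], flags["H3K27me3"]
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class TransitionSummary:
    """4x4 transition counts with per-cell mean log2 fold change."""

    counts: pd.DataFrame
    mean_log2fc: pd.DataFrame  # NaN marks empty cells
    members: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return int(self.counts.values.sum())


def transition_summary(
    states_a: Mapping[str, str],
    states_b: Mapping[str, str],
    expr: Sequence[ExpressionRecord] | Mapping[str, float],
) -> TransitionSummary:
    """Tabulate state transitions and the mean log2 FC per transition class.

    ``expr`` maps genes to linear fold changes (records or a mapping); genes
    without an expression value still count but do not enter the means.
    """
    if set(states_a) != set(states_b):
        raise ValueError("states_a and states_b cover different gene universes")
    if isinstance(expr, Mapping):
        fc = dict(expr)
    else:
        fc = {r.gene_id: r.fc for r in expr}
    counts = pd.DataFrame(0, index=list(STATES), columns=list(STATES))
    sums = pd.DataFrame(0.0, index=list(STATES), columns=list(STATES))
    ns = pd.DataFrame(0, index=list(STATES), columns=list(STATES))
    members: dict[tuple[str, str], list[str]] = {}
    for gene in sorted(states_a):
        sa, sb = states_a[gene], states_b[gene]
        counts.loc[sa, sb] += 1
        members.setdefault((sa, sb), []).append(gene)
        if gene in fc:
            sums.loc[sa, sb] += np.log2(fc[gene])
            ns.loc[sa, sb] += 1
    mean = sums / ns.replace(0, np.nan)
    return TransitionSummary(counts, mean, members)
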