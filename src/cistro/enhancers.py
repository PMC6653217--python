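"""Distal enhancer calling and gained/lost classification between cells.

Enhancers are H3K27ac peaks at least ``distal_min_bp`` from every TSS
(measured TSS to nearest peak edge).  The two cells' distal peaks are merged
into a union of regions; per-region tag counts are library-scaled and
compared with a Poisson tail test: a region is *gained* in cell B when the
pseudocounted ratio reaches ``min_fold`` with p below ``max_p``, *lost* for
the reciprocal, *stable* otherwise.  Each region is assigned the gene whose
TSS is nearest to its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionRecord, GeneModel, GenomicInterval, Peak


@dataclass
class EnhancerCall:
    """One enhancer-union region with its differential status."""

    interval: GenomicInterval
    tag_a: float
    tag_b: float
    log2_ratio: float
    p_value: float
    status: str  # gained / lost / stable
    nearest_gene: str
    distance_to_tss: float


def call_distal_enhancers(
    h3k27ac_peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    distal_min_bp: int = 2_000,
) -> list[Peak]:
    """Keep peaks whose nearest edge is >= ``distal_min_bp`` from every TSS."""
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    kept = []
    for p in h3k27ac_peaks:
        tss = tss_by_chrom.get(p.interval.chrom)
        if tss is None or len(tss) == 0:
            kept.append(p)
            continue
        # nearest TSS around either edge suffices: distance is monotone away
        idx = np.searchsorted(tss, [p.interval.start, p.interval.end])
        cand = tss[max(0, idx[0] - 1): idx[1] + 1]
        d = min(int(p.interval.distance_to_point(int(t))) for t in cand)
        if d >= distal_min_bp:
            kept.append(p)
    return kept


def merge_intervals(
    intervals: Sequence[GenomicInterval], gap_bp: int = 0
) -> list[GenomicInterval]:
    """Single-linkage merge of intervals whose gap is <= ``gap_bp``."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap_bp:
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def poisson_differential_test(
    tag_a: float,
    tag_b: float,
    lib_a: float,
    lib_b: float,
    scale_to: float = 1e7,
) -> tuple[float, float]:
    """Library-scaled Poisson tail test for a two-cell tag-count difference.

    Counts are scaled to a common library size, the ratio takes a +1
    pseudocount, and the p-value is the upper-tail Poisson probability of
    the larger scaled count under a rate of (smaller scaled count + 1).
    Swapping the cells flips the sign of the ratio but leaves p unchanged.
    """
    if tag_a < 0 or tag_b < 0:
        raise ValueError("tag counts must be non-negative")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    sa = tag_a * scale_to / lib_a
    sb = tag_b * scale_to / lib_b
    log2_ratio = float(np.log2((sb + 1.0) / (sa + 1.0)))
    lo, hi = min(sa, sb), max(sa, sb)
    p = float(stats.poisson.sf(round(hi) - 1, lo + 1.0))
    return log2_ratio, p


def nearest_gene(
    interval: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[str, float]:
    """Gene whose TSS is closest to the interval midpoint (ties: smallest id)."""
    same = [g for g in genes if g.chrom == interval.chrom]
    if not same:
        raise ValueError(f"no gene on chromosome {interval.chrom}")
    mid = interval.midpoint
    best = min(same, key=lambda g: (abs(g.tss - mid), g.gene_id))
    return best.gene_id, float(abs(best.tss - mid))


def classify_enhancer_changes(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    lib_a: float,
    lib_b: float,
    genes: Sequence[GeneModel],
    min_fold: float = 4.0,
    max_p: float = 1e-4,
    distal_min_bp: int = 2_000,
) -> list[EnhancerCall]:
    """Gained/lost/stable calls over the union of both cells' distal enhancers.

    ``peaks_a``/``peaks_b`` are each cell's H3K27ac peaks; the distal filter
    runs per cell, overlapping survivors are merged into union regions, and
    per-region tag counts per cell are the summed tags of that cell's
    overlapping peaks.
    """
    distal_a = call_distal_enhancers(peaks_a, genes, distal_min_bp)
    distal_b = call_distal_enhancers(peaks_b, genes, distal_min_bp)
    union = merge_intervals([p.interval for p in distal_a + distal_b])

    def _counts(peaks: Sequence[Peak]) -> dict[int, float]:
        starts = np.array([u.start for u in union])
        ends = np.array([u.end for u in union])
        totals = dict.fromkeys(range(len(union)), 0.0)
        for p in peaks:
            hits = np.nonzero((p.interval.start < ends) & (p.interval.end > starts))[0]
            for i in hits:
                if union[i].chrom == p.interval.chrom:
                    totals[int(i)] += p.tag_count
        return totals

    counts_a, counts_b = _counts(distal_a), _counts(distal_b)
    log_fold = np.log2(min_fold)
    calls: list[EnhancerCall] = []
    for i, region in enumerate(union):
        ratio, p = poisson_differential_test(counts_a[i], counts_b[i], lib_a, lib_b)
        if ratio >= log_fold and p < max_p:
            status = "gained"
        elif ratio <= -log_fold and p < max_p:
            status = "lost"
        else:
            status = "stable"
        gene, dist = nearest_gene(region, genes)
        calls.append(
            EnhancerCall(region, counts_a[i], counts_b[i], ratio, p, status, gene, dist)
        )
    return calls


_PROMOTER_CLASS = {
    True: "P-activated",
    False: "P-repressed",
}


def _promoter_class(state_a: str, state_b: str) -> str:
    if state_a == state_b:
        return "P-stable"
    if state_b == "Active":
        return "P-activated"
    if state_a == "Active" or state_b == "Repressive":
        return "P-repressed"
    return "P-other"


def synergy_table(
    transitions: Mapping[str, tuple[str, str]],
    calls: Sequence[EnhancerCall],
    degs: Sequence[ExpressionRecord],
) -> tuple[pd.DataFrame, pd.Series]:
    """Join each DEG to its promoter transition and assigned enhancer status.

    A gene's enhancer status is *gained* if any enhancer assigned to it was
    gained, else *lost* if any was lost, else *stable* if it has one, else
    *none*.  Returns the per-gene table and per-class mean log2 fold change.
    """
    by_gene: dict[str, list[EnhancerCall]] = {}
    for c in calls:
        by_gene.setdefault(c.nearest_gene, []).append(c)
    rows = []
    for r in degs:
        if r.gene_id not in transitions:
            continue
        sa, sb = transitions[r.gene_id]
        statuses = {c.status for c in by_gene.get(r.gene_id, [])}
        if "gained" in statuses:
            enh = "gained"
        elif "lost" in statuses:
            enh = "lost"
        elif statuses:
            enh = "stable"
        else:
            enh = "none"
        label = f"{_promoter_class(sa, sb)} & E-{enh}"
        rows.append(
            dict(gene_id=r.gene_id, state_a=sa, state_b=sb, enhancer_status=enh,
                 log2fc=r.log2fc, label=label)
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "state_a", "state_b", "enhancer_status",
                       "log2fc", "label"]
    )
    means = (
        table.groupby("label")["log2fc"].mean()
        if len(table)
        else pd.Series(dtype=float, name="log2fc")
    )
    return table, means
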