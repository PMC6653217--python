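"""Rank-ordering super-enhancer caller (stitch / rank / inflection cutoff).

H3K27ac peaks outside TSS-proximal windows are stitched when their gap is at
most 12.5 kb; stitched regions are ranked by increasing summed tag count,
both axes rescaled to [0, 1], and the cutoff is the signal at the first rank
where the one-step secant slope of the scaled curve exceeds 1.  Regions with
signal above the cutoff are super-enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GeneModel, GenomicInterval, Peak
from .enhancers import nearest_gene as _nearest_gene


@dataclass
class StitchedRegion:
    """A stitched candidate region with its ranked, scaled signal."""

    interval: GenomicInterval
    n_constituents: int
    signal: float
    rank: int | None = None
    scaled_rank: float | None = None
    scaled_signal: float | None = None
    is_super: bool = False
    nearest_gene: str | None = None


def stitch_peaks(
    peaks: Sequence[Peak],
    stitch_bp: int = 12_500,
    tss_exclusion_bp: int = 2_000,
    genes: Sequence[GeneModel] | None = None,
) -> list[StitchedRegion]:
    """Single-linkage merge of peaks whose gap is <= ``stitch_bp``.

    Peaks lying fully inside any TSS +/- ``tss_exclusion_bp`` window are
    removed before stitching (set ``tss_exclusion_bp=0`` or pass no genes to
    disable).  Region signal is the sum of constituent tag counts.
    """
    kept = list(peaks)
    if genes and tss_exclusion_bp > 0:
        tss_by_chrom: dict[str, list[int]] = {}
        for g in genes:
            tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
        def _excluded(p: Peak) -> bool:
            for t in tss_by_chrom.get(p.interval.chrom, ()):
                if p.interval.start >= t - tss_exclusion_bp and p.interval.end <= t + tss_exclusion_bp:
                    return True
            return False
        kept = [p for p in kept if not _excluded(p)]
    regions: list[StitchedRegion] = []
    for p in sorted(kept, key=lambda q: (q.interval.chrom, q.interval.start, q.interval.end)):
        if (
            regions
            and regions[-1].interval.chrom == p.interval.chrom
            and p.interval.start - regions[-1].interval.end <= stitch_bp
        ):
            last = regions[-1]
            regions[-1] = StitchedRegion(
                GenomicInterval(
                    last.interval.chrom,
                    last.interval.start,
                    max(last.interval.end, p.interval.end),
                ),
                last.n_constituents + 1,
                last.signal + p.tag_count,
            )
        else:
            regions.append(
                StitchedRegion(
                    GenomicInterval(p.interval.chrom, p.interval.start, p.interval.end),
                    1,
                    float(p.tag_count),
                )
            )
    return regions


def inflection_cutoff(signals: Sequence[float]) -> float:
    """Signal threshold at the inflection of the rank-ordered signal curve.

    Signals are sorted ascending and both rank and signal rescaled to
    [0, 1]; the cutoff is the (unscaled) signal at the left endpoint of the
    first one-rank secant whose slope strictly exceeds 1.  A linear curve
    (slope identically 1) or an all-equal profile yields no super-enhancers,
    signalled by an infinite cutoff.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 3:
        raise ValueError("inflection cutoff needs at least 3 regions")
    if s[-1] == s[0]:
        return float("inf")
    y = (s - s[0]) / (s[-1] - s[0])
    slopes = np.diff(y) * (n - 1)
    above = np.nonzero(slopes > 1.0 + 1e-12)[0]
    if len(above) == 0:
        return float("inf")
    return float(s[above[0]])


def call_super_enhancers(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel] | None = None,
    stitch_bp: int = 12_500,
    tss_exclusion_bp: int = 2_000,
) -> list[StitchedRegion]:
    """Stitch, rank and threshold; flags ``is_super`` and annotates genes.

    With fewer than 3 stitched regions no cutoff is defined and nothing is
    called super.
    """
    regions = stitch_peaks(peaks, stitch_bp, tss_exclusion_bp, genes)
    if not regions:
        return []
    regions.sort(key=lambda r: (r.signal, r.interval.chrom, r.interval.start))
    n = len(regions)
    smin, smax = regions[0].signal, regions[-1].signal
    cutoff = inflection_cutoff([r.signal for r in regions]) if n >= 3 else float("inf")
    span = (smax - smin) or 1.0
    for i, r in enumerate(regions):
        r.rank = i + 1
        r.scaled_rank = i / (n - 1) if n > 1 else 0.0
        r.scaled_signal = (r.signal - smin) / span
        r.is_super = r.signal > cutoff
        if genes:
            r.nearest_gene = _nearest_gene(r.interval, genes)[0]
    return regions


def compare_se_sets(
    se_a: Sequence[StitchedRegion],
    se_b: Sequence[StitchedRegion],
    min_overlap_bp: int = 1,
) -> tuple[list[StitchedRegion], list[StitchedRegion], list[tuple[StitchedRegion, StitchedRegion]]]:
    """Split two SE sets into (gained, lost, shared) by interval overlap.

    Shared pairs overlap by at least ``min_overlap_bp``; gained regions are
    B-only, lost are A-only.
    """
    shared: list[tuple[StitchedRegion, StitchedRegion]] = []
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    for i, a in enumerate(se_a):
        for j, b in enumerate(se_b):
            if a.interval.overlap_bp(b.interval) >= min_overlap_bp:
                shared.append((a, b))
                matched_a.add(i)
                matched_b.add(j)
    gained = [b for j, b in enumerate(se_b) if j not in matched_b]
    lost = [a for i, a in enumerate(se_a) if i not in matched_a]
    return gained, lost, shared
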