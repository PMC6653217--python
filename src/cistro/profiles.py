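"""Average tag-density profiles around TSS, stratified by expression.

The TSS +/-``window_bp`` region of each gene is split into ``n_bins`` equal
bins and the tag density (tags per kilobase per million library tags) is
computed per bin; genes are ranked into expression groups (deciles by
default, group 1 = top) and per-group mean curves are taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel


@dataclass
class TssProfileMatrix:
    """Normalized tag density around each gene's TSS.

    ``density`` is genes x bins, in tags per kilobase per million; ``bins``
    holds bin-midpoint offsets relative to the TSS, 5' to 3'.
    """

    genes: list[str]
    bins: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        if self.density.shape != (len(self.genes), len(self.bins)):
            raise ValueError("density shape must be (n_genes, n_bins)")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")


def bin_tag_density(
    tag_positions: Sequence[int] | np.ndarray,
    library_size: float,
    genes: Sequence[GeneModel],
    window_bp: int = 3_000,
    n_bins: int = 200,
) -> TssProfileMatrix:
    """Bin tag density over TSS +/- ``window_bp`` for every gene.

    Tags are single genomic positions (fragment midpoints).  The window of
    width ``2 * window_bp`` is split into ``n_bins`` bins (which must divide
    it evenly); a tag at offset d from the window start falls in bin
    ``floor(d / width)``.  Minus-strand profiles are reversed so bins run
    5' to 3'.  Density = count / (bin width in kb x library size in millions).
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if (2 * window_bp) % n_bins != 0:
        raise ValueError(f"{n_bins} bins do not divide a {2 * window_bp} bp window evenly")
    width = (2 * window_bp) // n_bins
    pos = np.sort(np.asarray(tag_positions, dtype=np.int64))
    scale = (width / 1_000.0) * (library_size / 1e6)
    density = np.zeros((len(genes), n_bins))
    for i, g in enumerate(genes):
        lo, hi = g.tss - window_bp, g.tss + window_bp
        sel = pos[np.searchsorted(pos, lo): np.searchsorted(pos, hi)]
        counts = np.bincount((sel - lo) // width, minlength=n_bins)[:n_bins]
        if g.strand == "-":
            counts = counts[::-1]
        density[i] = counts / scale
    mids = -window_bp + width * (np.arange(n_bins) + 0.5)
    return TssProfileMatrix([g.gene_id for g in genes], mids, density)


def expression_decile_groups(
    expr: Mapping[str, float], n_groups: int = 10
) -> dict[str, int]:
    """Rank genes into ``n_groups`` expression groups (1 = top decile).

    Group sizes differ by at most one; ties are broken by gene id so the
    split is deterministic.
    """
    if len(expr) < n_groups:
        raise ValueError(f"need at least {n_groups} genes, got {len(expr)}")
    ordered = sorted(expr, key=lambda g: (-expr[g], g))
    groups: dict[str, int] = {}
    for gidx, chunk in enumerate(np.array_split(np.array(ordered), n_groups), start=1):
        for gene in chunk:
            groups[str(gene)] = gidx
    return groups


def average_profiles(
    matrix: TssProfileMatrix, groups: Mapping[str, int]
) -> pd.DataFrame:
    """Per-group mean density curve; one column per group, rows are bins."""
    missing = [g for g in matrix.genes if g not in groups]
    if missing:
        raise ValueError(f"{len(missing)} profiled genes lack a group assignment")
    idx = {g: i for i, g in enumerate(matrix.genes)}
    out = {}
    for gidx in sorted(set(groups.values())):
        members = [idx[g] for g in matrix.genes if groups[g] == gidx]
        if not members:
            raise ValueError(f"group {gidx} has no member genes")
        out[gidx] = matrix.density[members].mean(axis=0)
    return pd.DataFrame(out, index=matrix.bins).rename_axis("offset")
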