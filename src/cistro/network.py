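"""Motif scanning, enrichment and TF-target network construction.

PWMs are scanned over element sequences with a log-odds score against a
background base composition; a window is a hit when its score reaches a
fraction of the PWM's maximum achievable score (deterministic, unlike a
per-PWM p-value threshold, and directly checkable against exhaustive word
enumeration).  Motif enrichment of target vs background elements is an
upper-tail hypergeometric test on element hit counts.  Edges link a TF to
the gene behind each hit element — proximal for promoters, distal for
enhancers, "both" when collapsed — and TF-TF cooperation is the Jaccard
index of target-gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Pwm

_BASES = "ACGT"
UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    element_id: str
    offset: int
    strand: str
    score: float


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)  # 4 = N / unknown
    for i, b in enumerate(_BASES):
        out[arr == ord(b)] = i
    return out


def _log_odds(pwm: Pwm, bg: Sequence[float]) -> np.ndarray:
    bg_arr = np.asarray(bg, dtype=float)
    if not np.isclose(bg_arr.sum(), 1.0, atol=1e-6):
        raise ValueError("background frequencies must sum to 1")
    with np.errstate(divide="ignore"):
        return np.log2(np.maximum(pwm.matrix, 1e-300) / bg_arr)


def max_score(pwm: Pwm, bg: Sequence[float] = UNIFORM_BG) -> float:
    """Best achievable log-odds score for this PWM."""
    return float(_log_odds(pwm, bg).max(axis=1).sum())


def _window_scores(lo: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Score every window of width(pwm); windows containing N get -inf."""
    w = lo.shape[0]
    L = len(enc) - w + 1
    if L <= 0:
        return np.empty(0)
    # column 4 (N) scores -inf, poisoning any window that covers it
    lo_ext = np.hstack([lo, np.full((w, 1), -np.inf)])
    scores = np.zeros(L)
    for j in range(w):
        scores += lo_ext[j, enc[j:j + L]]
    return scores


def scan_pwm(
    pwm: Pwm,
    sequence: str,
    element_id: str = "",
    bg: Sequence[float] = UNIFORM_BG,
    score_fraction: float = 0.8,
) -> list[MotifHit]:
    """Hits of ``pwm`` on both strands of ``sequence``.

    The score at an offset is sum_pos log2(p_pos(base)/bg(base)); an offset
    is a hit when its score reaches ``score_fraction`` times the maximum
    achievable score.  Minus-strand hits are reported at their forward-
    strand offset.  Windows containing N are skipped; a PWM wider than the
    sequence yields no hits.
    """
    lo = _log_odds(pwm, bg)
    threshold = score_fraction * float(lo.max(axis=1).sum())
    enc = _encode(sequence)
    hits: list[MotifHit] = []
    # reverse-complement scan: flip positions and complement columns
    for strand, mat in (("+", lo), ("-", lo[::-1, ::-1])):
        scores = _window_scores(mat, enc)
        for off in np.nonzero(scores >= threshold)[0]:
            hits.append(MotifHit(pwm.tf_name, element_id, int(off), strand,
                                 float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_elements(
    pwm: Pwm,
    sequences: Mapping[str, str],
    bg: Sequence[float] = UNIFORM_BG,
    score_fraction: float = 0.8,
) -> list[MotifHit]:
    """Scan many elements at once (N-separated concatenation, one pass)."""
    eids = sorted(sequences)
    if not eids:
        return []
    sep = 64  # wider than any realistic motif; N windows are skipped anyway
    parts, starts = [], []
    pos = 0
    for eid in eids:
        starts.append(pos)
        parts.append(_encode(sequences[eid]))
        pos += len(parts[-1]) + sep
        parts.append(np.full(sep, 4, dtype=np.int8))
    enc = np.concatenate(parts)
    lo = _log_odds(pwm, bg)
    threshold = score_fraction * float(lo.max(axis=1).sum())
    starts_arr = np.array(starts)
    hits: list[MotifHit] = []
    for strand, mat in (("+", lo), ("-", lo[::-1, ::-1])):
        scores = _window_scores(mat, enc)
        for off in np.nonzero(scores >= threshold)[0]:
            idx = int(np.searchsorted(starts_arr, off, side="right")) - 1
            hits.append(
                MotifHit(pwm.tf_name, eids[idx], int(off - starts_arr[idx]),
                         strand, float(scores[off]))
            )
    hits.sort(key=lambda h: (h.element_id, h.offset, h.strand))
    return hits


def motif_enrichment(
    pwm: Pwm,
    target_seqs: Mapping[str, str],
    background_seqs: Mapping[str, str],
    bg: Sequence[float] = UNIFORM_BG,
    score_fraction: float = 0.8,
) -> float:
    """Upper-tail hypergeometric p for motif presence in targets vs background.

    With N total elements, K carrying a hit, and n targets of which k carry
    a hit, p = P(X >= k) for X ~ Hypergeom(N, K, n).
    """
    if not target_seqs:
        raise ValueError("target element set is empty")
    if set(target_seqs) & set(background_seqs):
        raise ValueError("target and background element sets must be disjoint")
    k = sum(bool(scan_pwm(pwm, s, e, bg, score_fraction))
            for e, s in target_seqs.items())
    k_bg = sum(bool(scan_pwm(pwm, s, e, bg, score_fraction))
               for e, s in background_seqs.items())
    n, N = len(target_seqs), len(target_seqs) + len(background_seqs)
    K = k + k_bg
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class RegulatoryNetwork:
    """TF -> target-gene edges with proximal/distal/both evidence."""

    edges: pd.DataFrame  # columns tf, target, mode, cell
    cell: str = ""

    def targets(self, tf: str) -> set[str]:
        return set(self.edges.loc[self.edges["tf"] == tf, "target"])

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())


def build_network(
    promoter_hits: Sequence[MotifHit],
    enhancer_hits: Sequence[MotifHit],
    element_to_gene: Mapping[str, str],
    deg_genes: set[str] | None = None,
    restrict_tf_to_deg: bool = True,
    cell: str = "",
) -> RegulatoryNetwork:
    """Collapse motif hits into TF -> gene edges.

    Promoter hits give proximal edges, enhancer hits distal ones; a TF-gene
    pair supported by both collapses to mode "both".  With
    ``restrict_tf_to_deg`` only differentially expressed TFs enter the
    network.  Hits on elements without a gene assignment are skipped with a
    warning.
    """
    modes: dict[tuple[str, str], set[str]] = {}
    for hits, mode in ((promoter_hits, "proximal"), (enhancer_hits, "distal")):
        for h in hits:
            if restrict_tf_to_deg and deg_genes is not None and h.tf_name not in deg_genes:
                continue
            gene = element_to_gene.get(h.element_id)
            if gene is None:
                warnings.warn(f"element {h.element_id} has no gene assignment; "
                              f"edge skipped")
                continue
            modes.setdefault((h.tf_name, gene), set()).add(mode)
    rows = [
        dict(tf=tf, target=gene,
             mode="both" if len(ms) == 2 else next(iter(ms)), cell=cell)
        for (tf, gene), ms in sorted(modes.items())
    ]
    return RegulatoryNetwork(
        pd.DataFrame(rows, columns=["tf", "target", "mode", "cell"]), cell
    )


def jaccard_matrix(network: RegulatoryNetwork) -> pd.DataFrame:
    """Pairwise Jaccard index of TF target sets (TFs with targets only)."""
    tfs = [tf for tf in network.tfs if network.targets(tf)]
    sets = {tf: network.targets(tf) for tf in tfs}
    mat = pd.DataFrame(0.0, index=tfs, columns=tfs)
    for i, a in enumerate(tfs):
        for b in tfs[i:]:
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            ji = inter / union if union else 0.0
            mat.loc[a, b] = ji
            mat.loc[b, a] = ji
    return mat


def hub_factors(
    matrix: pd.DataFrame, ji_min: float = 0.3, min_partners: int = 10
) -> list[str]:
    """TFs cooperating (JI strictly > ``ji_min``) with strictly more than
    ``min_partners`` other factors."""
    hubs = []
    for tf in matrix.index:
        partners = sum(
            1 for other in matrix.columns
            if other != tf and matrix.loc[tf, other] > ji_min
        )
        if partners > min_partners:
            hubs.append(tf)
    return hubs
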