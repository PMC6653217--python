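"""Seeded synthetic study generator with ground truth.

Emits everything the analysis consumes — a toy genome, per-cell histone-mark
peak calls with Poisson tag counts, an expression table coupled to the
planted chromatin states, element sequences with exact-consensus motif
occurrences, hallmark-style gene sets, and a two-group patient cohort with
exponential survival — together with the ground-truth labels downstream
tests recover.

The generative model mirrors the assumptions of the analysis itself:

* each gene draws a (state in cell A, state in cell B) promoter-state pair;
  Active/Poised promoters carry H3K4me3 + H3K27ac peaks, Repressive/Poised
  promoters carry H3K27me3 (Repressive also H3K9me3);
* distal enhancers (H3K27ac + H3K4me1, 5-15 kb from the TSS) are gained,
  lost or stable with a configured intensity fold between cells;
* a fraction of loci carry >= 3 clustered high-signal enhancers in cell B
  within the stitching distance — the planted (gained) super-enhancers;
* log2 expression fold change = transition effect + enhancer effect + noise;
* motif consensus sequences are planted into cell-B-specific elements, with
  designated TF pairs co-occurring in the same element;
* cohort patients split into two latent groups with marker genes shifted in
  group 2, a higher metastasis rate there, and proportionally scaled
  exponential hazard.

All randomness flows from ``SimulationConfig.seed``; the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MARKS,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    Peak,
    Pwm,
    write_expression,
    write_gene_models,
    write_gmt,
    write_peaks,
    write_pwms,
)

STATES = ("Active", "Repressive", "Poised", "None")

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

HALLMARKS = (
    "SUSTAINING_PROLIFERATIVE_SIGNALING",
    "EVADING_GROWTH_SUPPRESSORS",
    "RESISTING_CELL_DEATH",
    "ENABLING_REPLICATIVE_IMMORTALITY",
    "INDUCING_ANGIOGENESIS",
    "ACTIVATING_INVASION_AND_METASTASIS",
    "GENOME_INSTABILITY_AND_MUTATION",
    "TUMOR_PROMOTING_INFLAMMATION",
    "DEREGULATING_CELLULAR_ENERGETICS",
    "AVOIDING_IMMUNE_DESTRUCTION",
)


def default_transition_probs() -> dict[tuple[str, str], float]:
    """Distribution over (state A, state B) promoter-state pairs.

    Mostly stable chromatin with an excess of activating transitions in the
    metastatic cell, matching the observed asymmetry (far more promoters
    activated than repressed).
    """
    return {
        ("Active", "Active"): 0.30,
        ("None", "None"): 0.20,
        ("Repressive", "Repressive"): 0.10,
        ("Poised", "Poised"): 0.05,
        ("Repressive", "Active"): 0.08,
        ("None", "Active"): 0.08,
        ("Poised", "Active"): 0.04,
        ("Active", "Repressive"): 0.04,
        ("Active", "None"): 0.04,
        ("None", "Repressive"): 0.03,
        ("Active", "Poised"): 0.02,
        ("Repressive", "None"): 0.02,
    }


def default_transition_effects() -> dict[tuple[str, str], float]:
    """Mean log2 expression shift per promoter-state transition.

    Repressive-to-Active is the strongest activation (> 3 log2 units) and
    None-to-Repressive the strongest repression (< -3), with intermediate
    transitions in between; stable states shift nothing.
    """
    return {
        ("Repressive", "Active"): 3.2,
        ("None", "Active"): 2.0,
        ("Poised", "Active"): 1.5,
        ("Active", "Repressive"): -3.0,
        ("Active", "None"): -2.0,
        ("Active", "Poised"): -1.5,
        ("None", "Repressive"): -3.4,
        ("Repressive", "None"): 1.0,
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the study conditions."""

    seed: int = 0
    # genome
    n_genes: int = 500
    chrom: str = "chrS"
    chrom_length_bp: int | None = None  # derived from spacing when None
    gene_spacing_bp: int = 40_000
    min_spacing_bp: int = 20_000
    tss_jitter_bp: int = 5_000
    marks: tuple[str, ...] = MARKS
    # chromatin
    state_transition_probs: dict[tuple[str, str], float] = field(
        default_factory=default_transition_probs
    )
    promoter_halfwidth_bp: int = 2_000
    promoter_peak_halfwidth_bp: int = 1_500
    mark_intensity: float = 100.0
    enhancer_intensity: float = 500.0
    enhancer_intensity_sigma: float = 0.5  # log-normal spread of base intensity
    enhancer_width_bp: int = 1_000
    enhancer_rate: float = 0.6
    enhancer_gain_rate: float = 0.15
    enhancer_loss_rate: float = 0.15
    enhancer_true_fold: float = 8.0
    se_fraction: float = 0.05
    se_n_constituents: int = 3
    se_intensity: float = 2_500.0
    se_background_fold: float = 50.0
    se_gained_frac: float = 0.6   # strong only in the metastatic cell
    se_stable_frac: float = 0.25  # strong in both (remainder: lost)
    depth_per_cell: float = 1e7
    noise_peak_rate_per_mb: float = 0.0
    # expression
    effect_log2fc_by_transition: dict[tuple[str, str], float] = field(
        default_factory=default_transition_effects
    )
    enhancer_effect_log2fc: float = 1.0
    se_effect_log2fc: float = 2.0
    baseline_log2_fpkm_mean: float = 4.0
    baseline_log2_fpkm_sd: float = 1.5
    noise_sd: float = 0.5
    # motifs
    n_tfs: int = 12
    pwm_width: int = 8
    pwm_consensus_prob: float = 0.85
    targets_per_tf: int = 50
    motif_cooccurrence_prob: float = 0.3
    tf_log2fc: float = 1.0
    # cohort
    n_patients: int = 404
    n_marker_genes: int = 30
    marker_delta_log2: float = 2.0
    met_rate_group1: float = 0.08
    met_rate_group2: float = 0.30
    hazard_ratio_per_marker: float = 3.0
    baseline_median_survival_months: float = 60.0
    censor_rate: float = 0.2
    # cell labels
    cell_a: str = "MDA_MB_231"
    cell_b: str = "LM2_4175"

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.depth_per_cell <= 0:
            raise ValueError("depth_per_cell must be > 0")
        probs = list(self.state_transition_probs.values())
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.isclose(sum(probs), 1.0, atol=1e-8):
            raise ValueError("state_transition_probs must sum to 1")
        for rate in (
            self.enhancer_rate,
            self.enhancer_gain_rate,
            self.enhancer_loss_rate,
            self.se_fraction,
            self.motif_cooccurrence_prob,
            self.censor_rate,
            self.met_rate_group1,
            self.met_rate_group2,
        ):
            if rate < 0 or rate > 1:
                raise ValueError("rates/probabilities must lie in [0, 1]")
        if self.chrom_length_bp is not None:
            needed = 2 * self._margin + (self.n_genes - 1) * self.min_spacing_bp + 1
            if self.chrom_length_bp < needed:
                raise ValueError(
                    f"chrom_length_bp {self.chrom_length_bp} too small for "
                    f"{self.n_genes} genes at >= {self.min_spacing_bp} bp spacing"
                )

    @property
    def _margin(self) -> int:
        return 50_000

    @property
    def chrom_length(self) -> int:
        if self.chrom_length_bp is not None:
            return self.chrom_length_bp
        return 2 * self._margin + self.n_genes * self.gene_spacing_bp


@dataclass
class EnhancerTruth:
    """A planted distal enhancer with its true differential status."""

    enh_id: str
    interval: GenomicInterval
    gene_id: str
    status: str  # gained / lost / stable
    intensity_a: float
    intensity_b: float
    se_id: str | None = None


@dataclass
class GroundTruth:
    """Planted labels the downstream analyses are expected to recover."""

    states: dict[str, tuple[str, str]] = field(default_factory=dict)
    enhancers: list[EnhancerTruth] = field(default_factory=list)
    se_regions: list[tuple[str, GenomicInterval, str, str]] = field(
        default_factory=list
    )  # (se_id, span, gene_id, status)
    expression_effect: dict[str, float] = field(default_factory=dict)
    tf_edges: set[tuple[str, str]] = field(default_factory=set)
    tf_element_hits: list[tuple[str, str, int]] = field(default_factory=list)
    marker_genes: list[str] = field(default_factory=list)
    patient_groups: dict[str, int] = field(default_factory=dict)


@dataclass
class SimulatedStudy:
    """In-memory bundle of all emitted artifacts plus their ground truth."""

    cfg: SimulationConfig
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    peaks: dict[tuple[str, str], list[Peak]]  # (cell, mark) -> peaks
    library_sizes: dict[tuple[str, str], float]
    expression: list[ExpressionRecord]
    pwms: list[Pwm]
    elements: pd.DataFrame  # element_id, kind, chrom, start, end, gene_id
    sequences: dict[str, str]
    gene_sets: dict[str, set[str]]
    cohort_expression: pd.DataFrame  # genes x patients
    cohort_clinical: pd.DataFrame
    truth: GroundTruth


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], dict[str, int]]:
    """Place ``n_genes`` TSS on one toy chromosome with guaranteed spacing.

    TSS positions sit on a regular grid with bounded jitter so that
    consecutive TSS are always >= ``min_spacing_bp`` apart and promoter
    windows never overlap.
    """
    cfg.validate()
    rng = rng if rng is not None else _rng(cfg, 1)
    length = cfg.chrom_length
    spacing = (
        cfg.gene_spacing_bp
        if cfg.chrom_length_bp is None
        else (length - 2 * cfg._margin) // cfg.n_genes
    )
    jitter = min(cfg.tss_jitter_bp, max((spacing - cfg.min_spacing_bp) // 2, 0))
    if spacing < cfg.min_spacing_bp:
        raise ValueError(
            f"cannot place {cfg.n_genes} genes at >= {cfg.min_spacing_bp} bp "
            f"spacing on a {length} bp chromosome"
        )
    genes: list[GeneModel] = []
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        tss = cfg._margin + i * spacing + int(rng.integers(-jitter, jitter + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        body = (
            GenomicInterval(cfg.chrom, tss, tss + 5_000, strand)
            if strand == "+"
            else GenomicInterval(cfg.chrom, max(0, tss - 4_999), tss + 1, strand)
        )
        genes.append(GeneModel(f"G{i + 1:0{width}d}", tss, strand, body))
    return genes, {cfg.chrom: length}


# ---------------------------------------------------------------------------
# chromatin
# ---------------------------------------------------------------------------


def _poisson_count(rng: np.random.Generator, cfg: SimulationConfig, intensity: float) -> int:
    return int(rng.poisson(intensity * cfg.depth_per_cell / 1e7))


def simulate_chromatin(
    cfg: SimulationConfig,
    genes: list[GeneModel],
    rng: np.random.Generator | None = None,
) -> tuple[dict[tuple[str, str], list[Peak]], GroundTruth]:
    """Emit per-cell, per-mark peaks realizing planted promoter states,
    gained/lost/stable distal enhancers and clustered super-enhancer loci."""
    rng = rng if rng is not None else _rng(cfg, 2)
    truth = GroundTruth()
    cells = (cfg.cell_a, cfg.cell_b)
    peaks: dict[tuple[str, str], list[Peak]] = {
        (cell, mark): [] for cell in cells for mark in cfg.marks
    }

    pairs = list(cfg.state_transition_probs.items())
    pair_idx = rng.choice(len(pairs), size=len(genes), p=[p for _, p in pairs])

    def _emit(cell: str, mark: str, interval: GenomicInterval, intensity: float, name: str) -> None:
        peaks[(cell, mark)].append(
            Peak(interval, mark, _poisson_count(rng, cfg, intensity), cell=cell, name=name)
        )

    # --- promoter marks -----------------------------------------------------
    half = cfg.promoter_peak_halfwidth_bp
    for gene, k in zip(genes, pair_idx):
        state_a, state_b = pairs[int(k)][0]
        truth.states[gene.gene_id] = (state_a, state_b)
        window = GenomicInterval(gene.chrom, max(0, gene.tss - half), gene.tss + half)
        for cell, state in zip(cells, (state_a, state_b)):
            name = f"prom:{gene.gene_id}"
            if state in ("Active", "Poised"):
                _emit(cell, "H3K4me3", window, cfg.mark_intensity, name)
                _emit(cell, "H3K27ac", window, cfg.mark_intensity, name)
            if state in ("Repressive", "Poised"):
                _emit(cell, "H3K27me3", window, cfg.mark_intensity, name)
            if state == "Repressive":
                _emit(cell, "H3K9me3", window, cfg.mark_intensity, name)

    # --- distal enhancers ---------------------------------------------------
    n = len(genes)
    order = rng.permutation(n)
    n_se = int(round(cfg.se_fraction * n))
    se_gene_idx = set(order[:n_se].tolist())
    rest = order[n_se:]
    n_enh = int(round(cfg.enhancer_rate * len(rest)))
    enh_gene_idx = rest[:n_enh]

    def _emit_enhancer(
        enh_id: str, gene: GeneModel, offset: int, int_a: float, int_b: float,
        status: str, se_id: str | None,
    ) -> EnhancerTruth:
        iv = GenomicInterval(gene.chrom, gene.tss + offset, gene.tss + offset + cfg.enhancer_width_bp)
        for cell, intensity in zip(cells, (int_a, int_b)):
            for mark in ("H3K27ac", "H3K4me1"):
                _emit(cell, mark, iv, intensity, enh_id)
        rec = EnhancerTruth(enh_id, iv, gene.gene_id, status, int_a, int_b, se_id)
        truth.enhancers.append(rec)
        return rec

    statuses = rng.random(len(enh_gene_idx))
    for j, gi in enumerate(enh_gene_idx):
        gene = genes[int(gi)]
        offset = int(rng.integers(5_000, 15_000 - cfg.enhancer_width_bp + 1))
        # continuous (log-normal) base intensity: real enhancer signal spans a
        # smooth range, which the rank-ordered inflection cutoff relies on
        base = float(
            rng.lognormal(np.log(cfg.enhancer_intensity), cfg.enhancer_intensity_sigma)
        )
        if statuses[j] < cfg.enhancer_gain_rate:
            status = "gained"
            int_a, int_b = base / cfg.enhancer_true_fold, base
        elif statuses[j] < cfg.enhancer_gain_rate + cfg.enhancer_loss_rate:
            status = "lost"
            int_a, int_b = base, base / cfg.enhancer_true_fold
        else:
            status = "stable"
            int_a = int_b = base
        _emit_enhancer(f"ENH_{gene.gene_id}", gene, offset, int_a, int_b, status, None)

    # --- super-enhancer loci: >= 3 clustered strong constituents -------------
    weak = cfg.se_intensity / cfg.se_background_fold
    strong = cfg.se_intensity
    for gi in sorted(se_gene_idx):
        gene = genes[int(gi)]
        se_id = f"SE_{gene.gene_id}"
        u = rng.random()
        if u < cfg.se_gained_frac:
            status, int_a, int_b = "gained", weak, strong
        elif u < cfg.se_gained_frac + cfg.se_stable_frac:
            status, int_a, int_b = "stable", strong, strong
        else:
            status, int_a, int_b = "lost", strong, weak
        offsets = [5_000 + 4_000 * c for c in range(cfg.se_n_constituents)]
        members = [
            _emit_enhancer(f"{se_id}_c{c + 1}", gene, off, int_a, int_b, status, se_id)
            for c, off in enumerate(offsets)
        ]
        span = GenomicInterval(
            gene.chrom, members[0].interval.start, members[-1].interval.end
        )
        truth.se_regions.append((se_id, span, gene.gene_id, status))

    # --- optional background noise peaks -------------------------------------
    if cfg.noise_peak_rate_per_mb > 0:
        length = cfg.chrom_length
        n_noise = int(round(cfg.noise_peak_rate_per_mb * length / 1e6))
        for cell in cells:
            for mark in cfg.marks:
                starts = rng.integers(0, length - 1_000, size=n_noise)
                for s in np.sort(starts):
                    _emit(
                        cell, mark,
                        GenomicInterval(cfg.chrom, int(s), int(s) + 1_000),
                        cfg.mark_intensity / 2, "noise",
                    )

    for key in peaks:
        peaks[key].sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks, truth


def simulate_tags(
    cfg: SimulationConfig,
    peaks: dict[tuple[str, str], list[Peak]],
    rng: np.random.Generator | None = None,
) -> tuple[dict[tuple[str, str], np.ndarray], dict[tuple[str, str], float]]:
    """Scatter each peak's tags uniformly over its interval.

    Returns per-(cell, mark) sorted tag positions and library sizes (the
    realized tag totals).
    """
    rng = rng if rng is not None else _rng(cfg, 3)
    positions: dict[tuple[str, str], np.ndarray] = {}
    libs: dict[tuple[str, str], float] = {}
    for key in sorted(peaks):
        chunks = [
            rng.integers(p.interval.start, p.interval.end, size=int(p.tag_count))
            for p in peaks[key]
        ]
        pos = np.sort(np.concatenate(chunks)) if chunks else np.empty(0, dtype=int)
        positions[key] = pos
        libs[key] = float(len(pos))
    return positions, libs


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def planted_log2fc(cfg: SimulationConfig, truth: GroundTruth, gene_id: str) -> float:
    """Deterministic (noise-free) planted log2 fold change for one gene."""
    effect = cfg.effect_log2fc_by_transition.get(truth.states[gene_id], 0.0)
    for enh in truth.enhancers:
        if enh.gene_id != gene_id:
            continue
        if enh.se_id is not None:
            continue  # super-enhancer effect counted once, below
        if enh.status == "gained":
            effect += cfg.enhancer_effect_log2fc
        elif enh.status == "lost":
            effect -= cfg.enhancer_effect_log2fc
    for _sid, _iv, g, status in truth.se_regions:
        if g == gene_id:
            if status == "gained":
                effect += cfg.se_effect_log2fc
            elif status == "lost":
                effect -= cfg.se_effect_log2fc
    return effect


def simulate_expression(
    cfg: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> list[ExpressionRecord]:
    """Couple expression fold change to the planted chromatin labels.

    log2(fpkm_b) - log2(fpkm_a) = transition effect + enhancer effect + noise.
    Planted (non-zero effect) genes receive small simulated q-values,
    unperturbed genes uniform ones.  TF genes are appended as up-regulated
    DEGs so the network stage's DEG restriction keeps them.
    """
    rng = rng if rng is not None else _rng(cfg, 4)
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    records: list[ExpressionRecord] = []
    for gene_id in sorted(truth.states):
        effect = planted_log2fc(cfg, truth, gene_id)
        truth.expression_effect[gene_id] = effect
        log2fc = effect + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        base = rng.normal(cfg.baseline_log2_fpkm_mean, cfg.baseline_log2_fpkm_sd)
        fpkm_a = float(2.0**base)
        fpkm_b = float(fpkm_a * 2.0**log2fc)
        if effect != 0.0:
            q = float(10.0 ** -rng.uniform(2.0, 6.0))
        else:
            q = float(rng.uniform(0.0, 1.0))
        records.append(
            ExpressionRecord(gene_id, fpkm_a, fpkm_b, fc=float(2.0**log2fc), q=q)
        )
    # TF genes: up-regulated so they survive the DEG restriction
    for t in range(cfg.n_tfs):
        tf = f"TF{t + 1:02d}"
        fpkm_a = float(2.0**cfg.baseline_log2_fpkm_mean)
        log2fc = cfg.tf_log2fc + (rng.normal(0.0, 0.1) if sd > 0 else 0.0)
        records.append(
            ExpressionRecord(tf, fpkm_a, float(fpkm_a * 2.0**log2fc),
                             fc=float(2.0**log2fc), q=1e-3)
        )
    return records


# ---------------------------------------------------------------------------
# motifs and sequences
# ---------------------------------------------------------------------------


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def make_synthetic_pwms(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[Pwm]:
    """High-information PWMs with pairwise-distinct, non-palindromic consensus.

    The consensus base carries ``pwm_consensus_prob`` at every position, so
    at the default 0.8 fraction-of-max scan threshold only the exact
    consensus (or its reverse complement) scores as a hit — planted
    occurrences are recovered deterministically.
    """
    rng = rng if rng is not None else _rng(cfg, 5)
    p = cfg.pwm_consensus_prob
    off = (1.0 - p) / 3.0
    taken: set[str] = set()
    pwms: list[Pwm] = []
    while len(pwms) < cfg.n_tfs:
        cons = "".join(_BASES[i] for i in rng.integers(0, 4, size=cfg.pwm_width))
        rc = _revcomp(cons)
        if cons == rc or cons in taken or rc in taken:
            continue
        taken.update((cons, rc))
        matrix = np.full((cfg.pwm_width, 4), off)
        for pos, base in enumerate(cons):
            matrix[pos, _BASES.index(base)] = p
        pwms.append(Pwm(f"TF{len(pwms) + 1:02d}", matrix))
    return pwms


def simulate_sequences_with_motifs(
    cfg: SimulationConfig,
    elements: pd.DataFrame,
    pwms: list[Pwm],
    truth: GroundTruth,
    target_element_ids: list[str],
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Uniform-background sequences with exact-consensus motifs planted.

    ``elements`` must carry element_id / gene_id / start / end columns.  For
    every TF, ``targets_per_tf`` elements are drawn from
    ``target_element_ids``; designated TF pairs (1-2, 3-4, ...) co-occur in
    the same element with probability ``motif_cooccurrence_prob``.  True
    TF->gene edges and element-level occurrences are recorded on ``truth``.
    """
    rng = rng if rng is not None else _rng(cfg, 6)
    lengths = {
        str(r.element_id): int(r.end) - int(r.start)
        for r in elements.itertuples(index=False)
    }
    gene_of = {
        str(r.element_id): str(r.gene_id) for r in elements.itertuples(index=False)
    }
    seqs: dict[str, np.ndarray] = {
        eid: rng.integers(0, 4, size=lengths[eid]).astype(np.uint8)
        for eid in sorted(lengths)
    }
    occupied: dict[str, list[tuple[int, int]]] = {eid: [] for eid in seqs}

    def _plant(tf_idx: int, eid: str) -> None:
        pwm = pwms[tf_idx]
        w = pwm.width
        if lengths[eid] < w:
            raise ValueError(f"element {eid} shorter than motif width {w}")
        cons = np.array([_BASES.index(b) for b in pwm.consensus], dtype=np.uint8)
        for _ in range(50):  # re-draw on collision with an earlier motif
            offset = int(rng.integers(0, lengths[eid] - w + 1))
            if all(offset + w <= s or offset >= e for s, e in occupied[eid]):
                break
        else:
            return
        seqs[eid][offset:offset + w] = cons
        occupied[eid].append((offset, offset + w))
        truth.tf_element_hits.append((pwm.tf_name, eid, offset))
        truth.tf_edges.add((pwm.tf_name, gene_of[eid]))

    pool = [eid for eid in target_element_ids if eid in seqs]
    if pool:
        for t in range(len(pwms)):
            k = min(cfg.targets_per_tf, len(pool))
            chosen = rng.choice(len(pool), size=k, replace=False)
            partner = t + 1 if t % 2 == 0 else t - 1
            for ci in chosen:
                eid = pool[int(ci)]
                _plant(t, eid)
                if partner < len(pwms) and rng.random() < cfg.motif_cooccurrence_prob:
                    _plant(partner, eid)
    return {eid: "".join(_BASES[b] for b in arr) for eid, arr in seqs.items()}


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    cfg: SimulationConfig,
    marker_genes: list[str],
    null_genes: list[str] | None = None,
    down_marker_genes: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Two latent patient groups with shifted markers and exponential survival.

    Group-2 patients have marker genes up-shifted by ``marker_delta_log2``
    (``down_marker_genes``, when given, shift down by the same amount, as a
    DEG panel carries both directions), a higher metastasis rate, and their
    hazard multiplied by ``hazard_ratio_per_marker``.  Censoring is
    independent: with probability ``censor_rate`` a patient is censored
    uniformly before their event.  Returns (expression genes x patients,
    clinical table, true groups).
    """
    if not marker_genes:
        raise ValueError("need at least one marker gene")
    rng = rng if rng is not None else _rng(cfg, 7)
    n = cfg.n_patients
    group = (rng.random(n) < 0.5).astype(int) + 1  # 1 or 2
    patients = [f"P{i + 1:04d}" for i in range(n)]
    down = list(down_marker_genes or [])
    genes = list(marker_genes) + down + list(null_genes or [])
    base = rng.normal(5.0, 1.0, size=(len(genes), n))
    shift = np.zeros((len(genes), n))
    shift[: len(marker_genes), :] = cfg.marker_delta_log2 * (group == 2)
    shift[len(marker_genes): len(marker_genes) + len(down), :] = (
        -cfg.marker_delta_log2 * (group == 2)
    )
    expr = pd.DataFrame(2.0 ** (base + shift), index=genes, columns=patients)
    expr.index.name = "gene_id"

    met_rate = np.where(group == 2, cfg.met_rate_group2, cfg.met_rate_group1)
    metastasis = (rng.random(n) < met_rate).astype(int)
    base_rate = np.log(2.0) / cfg.baseline_median_survival_months
    hazard = base_rate * np.where(group == 2, cfg.hazard_ratio_per_marker, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < cfg.censor_rate
    time = np.where(censored, rng.uniform(0.0, 1.0, size=n) * t_event, t_event)
    event = (~censored).astype(int)

    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "time": np.round(time, 4),
            "event": event,
            "metastasis_label": metastasis,
            "er_status": "negative",
        }
    )
    return expr, clinical, dict(zip(patients, group.tolist()))


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def _element_table(
    cfg: SimulationConfig, genes: list[GeneModel], truth: GroundTruth
) -> pd.DataFrame:
    rows = []
    half = cfg.promoter_halfwidth_bp
    for g in genes:
        rows.append(
            dict(element_id=f"PROM_{g.gene_id}", kind="promoter", chrom=g.chrom,
                 start=max(0, g.tss - half), end=g.tss + half, gene_id=g.gene_id)
        )
    for enh in truth.enhancers:
        rows.append(
            dict(element_id=enh.enh_id, kind="enhancer", chrom=enh.interval.chrom,
                 start=enh.interval.start, end=enh.interval.end, gene_id=enh.gene_id)
        )
    return pd.DataFrame(rows)


def _motif_target_pool(truth: GroundTruth) -> list[str]:
    """Cell-B-specific elements: promoters newly Active in B + gained enhancers."""
    pool = [
        f"PROM_{g}" for g, (sa, sb) in sorted(truth.states.items())
        if sb == "Active" and sa != "Active"
    ]
    pool += [e.enh_id for e in truth.enhancers if e.status == "gained"]
    return pool


def _gene_sets(
    cfg: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> dict[str, set[str]]:
    changed = sorted(
        {g for g, (sa, sb) in truth.states.items() if sa != sb}
        | {e.gene_id for e in truth.enhancers if e.status != "stable"}
        | {g for g, eff in truth.expression_effect.items() if eff != 0.0}
    )
    unchanged = sorted(set(truth.states) - set(changed))
    sets: dict[str, set[str]] = {}
    for name in HALLMARKS:
        bias = rng.uniform(0.2, 0.8)
        k_changed = int(round(bias * 40))
        pick_c = rng.choice(len(changed), size=min(k_changed, len(changed)), replace=False)
        pick_u = rng.choice(
            len(unchanged), size=min(40 - k_changed, len(unchanged)), replace=False
        )
        sets[name] = {changed[i] for i in pick_c} | {unchanged[i] for i in pick_u}
    return sets


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run every generator in a fixed order under a single master seed."""
    cfg.validate()
    genes, chrom_sizes = simulate_genome(cfg)
    peaks, truth = simulate_chromatin(cfg, genes)
    # the library size is total sequencing depth, which the generator fixes
    # per cell; in-peak tags are only a small fraction of a real library
    library_sizes = {key: float(cfg.depth_per_cell) for key in peaks}
    expression = simulate_expression(cfg, truth)
    pwms = make_synthetic_pwms(cfg)
    elements = _element_table(cfg, genes, truth)
    sequences = simulate_sequences_with_motifs(
        cfg, elements, pwms, truth, _motif_target_pool(truth)
    )
    gene_sets = _gene_sets(cfg, truth, _rng(cfg, 8))
    by_effect = sorted(truth.expression_effect.items(), key=lambda kv: -kv[1])
    markers = [g for g, eff in by_effect if eff > 0][: cfg.n_marker_genes]
    down_markers = [g for g, eff in by_effect[::-1] if eff < 0][: cfg.n_marker_genes]
    cohort_expr, clinical, groups = simulate_cohort(
        cfg, markers, null_genes=None, down_marker_genes=down_markers
    )
    truth.marker_genes = markers
    truth.patient_groups = groups
    return SimulatedStudy(
        cfg=cfg,
        genes=genes,
        chrom_sizes=chrom_sizes,
        peaks=peaks,
        library_sizes=library_sizes,
        expression=expression,
        pwms=pwms,
        elements=elements,
        sequences=sequences,
        gene_sets=gene_sets,
        cohort_expression=cohort_expr,
        cohort_clinical=clinical,
        truth=truth,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write every artifact in the exact formats the readers consume."""
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    write_gene_models(study.genes, out / "genes.bed")
    with open(out / "chrom.sizes", "w") as fh:
        for chrom, size in study.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    for (cell, mark), plist in sorted(study.peaks.items()):
        write_peaks(plist, out / "peaks" / f"{cell}.{mark}.bed")
    with open(out / "library_sizes.tsv", "w") as fh:
        fh.write("cell\tmark\tlibrary_size\n")
        for (cell, mark), lib in sorted(study.library_sizes.items()):
            fh.write(f"{cell}\t{mark}\t{int(lib)}\n")
    write_expression(study.expression, out / "expression.tsv")
    write_pwms(study.pwms, out / "pwms.jaspar")
    study.elements.to_csv(out / "elements.tsv", sep="\t", index=False)
    with open(out / "elements.fa", "w") as fh:
        for eid in sorted(study.sequences):
            fh.write(f">{eid}\n{study.sequences[eid]}\n")
    write_gmt({k: sorted(v) for k, v in study.gene_sets.items()}, out / "genesets.gmt")
    study.cohort_expression.to_csv(out / "cohort_expression.tsv", sep="\t")
    study.cohort_clinical.to_csv(out / "cohort_clinical.tsv", sep="\t", index=False)

    t = study.truth
    pd.DataFrame(
        [(g, sa, sb) for g, (sa, sb) in sorted(t.states.items())],
        columns=["gene_id", "state_a", "state_b"],
    ).to_csv(out / "truth" / "promoter_states.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (e.enh_id, e.interval.chrom, e.interval.start, e.interval.end,
             e.gene_id, e.status, e.intensity_a, e.intensity_b, e.se_id or "")
            for e in t.enhancers
        ],
        columns=["enh_id", "chrom", "start", "end", "gene_id", "status",
                 "intensity_a", "intensity_b", "se_id"],
    ).to_csv(out / "truth" / "enhancers.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (sid, iv.chrom, iv.start, iv.end, g, status)
            for sid, iv, g, status in t.se_regions
        ],
        columns=["se_id", "chrom", "start", "end", "gene_id", "status"],
    ).to_csv(out / "truth" / "super_enhancers.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(t.tf_edges), columns=["tf", "gene_id"]
    ).to_csv(out / "truth" / "tf_edges.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(t.patient_groups.items()), columns=["patient_id", "group"]
    ).to_csv(out / "truth" / "patient_groups.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": t.marker_genes}).to_csv(
        out / "truth" / "marker_genes.tsv", sep="\t", index=False
    )


def audit_consistency(study: SimulatedStudy) -> list[str]:
    """Cross-check emitted artifacts against the ground truth.

    Returns a list of inconsistency descriptions (empty when clean).  With
    noise peaks off, every emitted peak must trace back to a truth record.
    """
    issues: list[str] = []
    t = study.truth
    enh_ids = {e.enh_id for e in t.enhancers}
    for (cell, mark), plist in study.peaks.items():
        for p in plist:
            if p.name.startswith("prom:"):
                gene = p.name.split(":", 1)[1]
                if gene not in t.states:
                    issues.append(f"promoter peak for unknown gene {gene}")
            elif p.name == "noise":
                if study.cfg.noise_peak_rate_per_mb == 0:
                    issues.append(f"noise peak emitted with noise rate 0 ({cell}/{mark})")
            elif p.name not in enh_ids:
                issues.append(f"peak {p.name} has no truth record")
    expr_genes = {r.gene_id for r in study.expression}
    missing = set(t.states) - expr_genes
    if missing:
        issues.append(f"{len(missing)} genes missing from the expression table")
    for tf, eid, offset in t.tf_element_hits:
        pwm = next(p for p in study.pwms if p.tf_name == tf)
        seq = study.sequences[eid]
        if seq[offset:offset + pwm.width] != pwm.consensus:
            issues.append(f"planted motif {tf} absent from {eid} at {offset}")
    for sid, iv, gene, _status in t.se_regions:
        members = [e for e in t.enhancers if e.se_id == sid]
        if len(members) < study.cfg.se_n_constituents:
            issues.append(f"{sid} has fewer constituents than configured")
        if members and (members[0].interval.start != iv.start
                        or members[-1].interval.end != iv.end):
            issues.append(f"{sid} span inconsistent with constituents")
    if set(study.truth.patient_groups) != set(study.cohort_expression.columns):
        issues.append("patient groups and cohort expression columns differ")
    return issues
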