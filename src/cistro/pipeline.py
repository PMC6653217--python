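"""End-to-end orchestration of all analysis stages with a manifest.

``run_all`` executes the stages in dependency order on a directory of input
files (as written by :func:`cistro.simulate.write_study` or assembled from
real data in the same formats), writes each stage's tables into the run
directory, and records a reproducibility manifest (config hash, seed,
package version, per-stage row counts and output checksums).  All stages
are deterministic given the config seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .cohort import contingency_chisq, logrank_test, nmf_cluster, split_by_mean
from .enhancers import classify_enhancer_changes, synergy_table
from .functional import geneset_enrichment, hallmark_percentages
from .io import (
    MARKS,
    ExpressionRecord,
    GeneModel,
    Peak,
    Pwm,
    filter_degs,
    parse_expression,
    parse_gene_models,
    parse_gmt,
    parse_peaks,
    parse_pwms,
)
from .network import build_network, hub_factors, jaccard_matrix, scan_elements
from .profiles import average_profiles, bin_tag_density, expression_decile_groups
from .promoters import classify_promoters, transition_summary
from .superenhancers import call_super_enhancers, compare_se_sets
from scipy import stats


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """All stage thresholds plus input location and master seed.

    Defaults follow the published thresholds where one is stated (promoter
    half-width 2 kb; 2 kb distal rule; 4-fold / p < 1e-4 differential
    enhancers; 12.5 kb stitching; motif p < 1e-10; JI > 0.3 with > 10
    partners; DEG >= 1.5-fold, q < 0.05; FDR <= 0.05; TSS +/- 3 kb in 200
    bins; k = 2 clusters).
    """

    data_dir: str = "."
    seed: int = 0
    cell_a: str = "MDA_MB_231"
    cell_b: str = "LM2_4175"
    promoter_halfwidth_bp: int = 2_000
    distal_min_bp: int = 2_000
    min_fold: float = 4.0
    max_p: float = 1e-4
    stitch_bp: int = 12_500
    tss_exclusion_bp: int = 2_000
    motif_p: float = 1e-10
    score_fraction: float = 0.8
    ji_min: float = 0.3
    min_partners: int = 10
    deg_min_fc: float = 1.5
    deg_max_q: float = 0.05
    max_fdr: float = 0.05
    profile_window_bp: int = 3_000
    n_bins: int = 200
    k: int = 2
    n_restarts: int = 30

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class StudyInputs:
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    peaks: dict[tuple[str, str], list[Peak]]
    library_sizes: dict[tuple[str, str], float]
    expression: list[ExpressionRecord]
    pwms: list[Pwm]
    elements: pd.DataFrame
    sequences: dict[str, str]
    gene_sets: dict[str, set[str]]
    cohort_expression: pd.DataFrame | None
    cohort_clinical: pd.DataFrame | None


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def load_inputs(data_dir: str | Path) -> StudyInputs:
    """Load every input the stages consume from one directory."""
    d = Path(data_dir)
    genes = parse_gene_models(_require(d / "genes.bed"))
    chrom_sizes = {}
    for line in _require(d / "chrom.sizes").read_text().splitlines():
        chrom, size = line.split("\t")
        chrom_sizes[chrom] = int(size)
    peaks: dict[tuple[str, str], list[Peak]] = {}
    for bed in sorted((d / "peaks").glob("*.bed")):
        cell, mark = bed.stem.rsplit(".", 1)
        peaks[(cell, mark)] = parse_peaks(bed, mark=mark, cell=cell)
    libs = pd.read_csv(_require(d / "library_sizes.tsv"), sep="\t")
    library_sizes = {
        (r.cell, r.mark): float(r.library_size) for r in libs.itertuples(index=False)
    }
    expression = parse_expression(_require(d / "expression.tsv"))
    pwms = parse_pwms(_require(d / "pwms.jaspar"))
    elements = pd.read_csv(_require(d / "elements.tsv"), sep="\t")
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(_require(d / "elements.fa")), "fasta")
    }
    gene_sets = parse_gmt(_require(d / "genesets.gmt"))
    cohort_expr = cohort_clin = None
    if (d / "cohort_expression.tsv").exists():
        cohort_expr = pd.read_csv(d / "cohort_expression.tsv", sep="\t", index_col=0)
        cohort_clin = pd.read_csv(_require(d / "cohort_clinical.tsv"), sep="\t")
    return StudyInputs(genes, chrom_sizes, peaks, library_sizes, expression,
                       pwms, elements, sequences, gene_sets, cohort_expr, cohort_clin)


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> int:
    df.to_csv(path, sep="\t", index=index)
    return len(df)


def _spread_tags(
    peaks: list[Peak], seed: int
) -> np.ndarray:
    """Deterministically scatter each peak's tags uniformly over the peak."""
    rng = np.random.default_rng([seed, 17])
    chunks = [
        rng.integers(p.interval.start, p.interval.end, size=int(p.tag_count))
        for p in peaks
    ]
    return np.sort(np.concatenate(chunks)) if chunks else np.empty(0, dtype=int)


# ---------------------------------------------------------------------------
# stages — each returns {"rows": int} and writes its outputs under ``out``
# ---------------------------------------------------------------------------


def stage_inputs(cfg: RunConfig, inp: StudyInputs, ctx: dict, out: Path) -> dict:
    degs = filter_degs(inp.expression, cfg.deg_min_fc, cfg.deg_max_q)
    ctx["degs"] = degs
    df = pd.DataFrame(
        [(r.gene_id, r.fpkm_a, r.fpkm_b, r.fc, r.q, r.direction) for r in degs],
        columns=["gene_id", "fpkm_a", "fpkm_b", "fc", "q", "direction"],
    )
    return {"rows": _write(df, out / "degs.tsv")}


def stage_profiles(cfg: RunConfig, inp: StudyInputs, ctx: dict, out: Path) -> dict:
    expr_by_cell = {
        cfg.cell_a: {r.gene_id: r.fpkm_a for r in inp.expression},
        cfg.cell_b: {r.gene_id: r.fpkm_b for r in inp.expression},
    }
    gene_ids = {g.gene_id for g in inp.genes}
    frames = []
    for (cell, mark), plist in sorted(inp.peaks.items()):
        tags = _spread_tags(plist, cfg.seed)
        lib = inp.library_sizes.get((cell, mark)) or max(float(len(tags)), 1.0)
        matrix = bin_tag_density(tags, lib, inp.genes, cfg.profile_window_bp, cfg.n_bins)
        expr = {g: v for g, v in expr_by_cell[cell].items() if g in gene_ids}
        groups = expression_decile_groups(expr)
        prof = average_profiles(matrix, groups)
        long = prof.reset_index().melt("offset", var_name="group", value_name="density")
        long.insert(0, "mark", mark)
        long.insert(0, "cell", cell)
        frames.append(long)
    df = pd.concat(frames, ignore_index=True)
    ctx["profiles"] = df
    return {"rows": _write(df, out / "profiles.tsv")}


def stage_promoters(cfg: RunConfig, inp: StudyInputs, ctx: dict, out: Path) -> dict:
    states = {}
    tables = []
    for cell in (cfg.cell_a, cfg.cell_b):
        by_mark = {m: inp.peaks.get((cell, m), []) for m in MARKS}
        table = classify_promoters(
            inp.genes, by_mark, cfg.promoter_halfwidth_bp,
            chrom_sizes=inp.chrom_sizes,
        )
        states[cell] = table["state"].to_dict()
        table = table.add_prefix(f"{cell}.")
        tables.append(table)
    merged = pd.concat(tables, axis=1)
    merged.insert(0, "state_b", merged.pop(f"{cfg.cell_b}.state"))
    merged.insert(0, "state_a", merged.pop(f"{cfg.cell_a}.state"))
    fc = {r.gene_id: r.fc for r in inp.expression}
    summary = transition_summary(states[cfg.cell_a], states[cfg.cell_b], fc)
    ctx["states_a"], ctx["states_b"] = states[cfg.cell_a], states[cfg.cell_b]
    ctx["transitions"] = summary
    _write(merged, out / "promoter_states.tsv", index=True)
    summary.counts.rename_axis("state_a").to_csv(out / "transition_counts.tsv", sep="\t")
    summary.mean_log2fc.rename_axis("state_a").to_csv(
        out / "transition_mean_log2fc.tsv", sep="\t"
    )
    return {"rows": len(merged)}


def stage_enhancers(cfg: RunConfig, inp: StudyInputs, ctx: dict, out: Path) -> dict:
    calls = classify_enhancer_changes(
        inp.peaks.get((cfg.cell_a, "H3K27ac"), []),
        inp.peaks.get((cfg.cell_b, "H3K27ac"), []),
        inp.library_sizes[(cfg.cell_a, "H3K27ac")],
        inp.library_sizes[(cfg.cell_b, "H3K27ac")],
        inp.genes,
        cfg.min_fold,
        cfg.max_p,
        cfg.distal_min_bp,
    )
    ctx["enhancer_calls"] = calls
    df = pd.DataFrame(
        [
            (c.interval.chrom, c.interval.start, c.interval.end, c.tag_a, c.tag_b,
             c.log2_ratio, c.p_value, c.status, c.nearest_gene, c.distance_to_tss)
            for c in calls
        ],
        columns=["chrom", "start", "end", "tag_a", "tag_b", "log2_ratio", "p",
                 "status", "nearest_gene", "distance_to_tss"],
    )
    return {"rows": _write(df, out / "enhancers.tsv")}


def stage_synergy(cfg: RunConfig, inp: StudyInputs, ctx: dict, out: Path) -> dict:
    transitions = {
        g: (ctx["states_a"][g], ctx["states_b"][g]) for g in ctx["states_a"]
    }
    table, means = synergy_table(transitions, ctx["enhancer_calls"], ctx["degs"])
    ctx["synergy"] = table
    _write(means.reset_index(), out / "synergy_mean_log2fc.tsv")
    return {"rows": _write(table, out / "synergy.tsv")}


def stage_superenhancers(cfg: RunConfig, inp: StudyInputs, ctx: dict, out: Path) -> dict:
    se_sets = {}
    n_rows = 0
    for cell in (cfg.cell_a, cfg.cell_b):
        regions = call_super_enhancers(
            inp.peaks.get((cell, "H3K27ac"), []), inp.genes,
            cfg.stitch_bp, cfg.tss_exclusion_bp,
        )
        se_sets[cell] = [r for r in regions if r.is_super]
        df = pd.DataFrame(
            [
                (r.interval.chrom, r.interval.start, r.interval.end,
                 r.n_constituents, r.signal, r.rank, r.scaled_rank,
                 r.scaled_signal, r.is_super, r.nearest_gene)
                for r in regions
            ],
            columns=["chrom", "start", "end", "n_constituents", "signal", "rank",
                     "scaled_rank", "scaled_signal", "is_super", "nearest_gene"],
        )
        n_rows += _write(df, out / f"stitched_{cell}.tsv")
    gained, lost, shared = compare_se_sets(se_sets[cfg.cell_a], se_sets[cfg.cell_b])
    ctx["se_gained"], ctx["se_lost"], ctx["se_shared"] = gained, lost, shared
    summary = pd.DataFrame(
        [
            ("super_enhancers_" + cfg.cell_a, len(se_sets[cfg.cell_a])),
            ("super_enhancers_" + cfg.cell_b, len(se_sets[cfg.cell_b])),
            ("gained", len(gained)),
            ("lost", len(lost)),
            ("shared_pairs", len(shared)),
        ],
        columns=["quantity", "count"],
    )
    _write(summary, out / "se_comparison.tsv")
    return {"rows": n_rows}


def _cell_specific_elements(cfg: RunConfig, inp: StudyInputs, ctx: dict) -> dict:
    """Element ids exclusive to each cell's active set.

    Promoters: genes Active in one cell and not the other.  Enhancer
    elements: overlap with a gained call makes them B-specific, with a lost
    call A-specific.
    """
    spec = {cfg.cell_a: {"promoter": set(), "enhancer": set()},
            cfg.cell_b: {"promoter": set(), "enhancer": set()}}
    for g in ctx["states_a"]:
        a_active = ctx["states_a"][g] == "Active"
        b_active = ctx["states_b"][g] == "Active"
        if b_active and not a_active:
            spec[cfg.cell_b]["promoter"].add(f"PROM_{g}")
        elif a_active and not b_active:
            spec[cfg.cell_a]["promoter"].add(f"PROM_{g}")
    enh_elements = inp.elements[inp.elements["kind"] == "enhancer"]
    for row in enh_elements.itertuples(index=False):
        for c in ctx["enhancer_calls"]:
            if (c.interval.chrom == row.chrom
                    and c.interval.start < row.end and c.interval.end > row.start):
                if c.status == "gained":
                    spec[cfg.cell_b]["enhancer"].add(row.element_id)
                elif c.status == "lost":
                    spec[cfg.cell_a]["enhancer"].add(row.element_id)
                break
    return spec


def stage_network(cfg: RunConfig, inp: StudyInputs, ctx: dict, out: Path) -> dict:
    spec = _cell_specific_elements(cfg, inp, ctx)
    gene_of = dict(zip(inp.elements["element_id"], inp.elements["gene_id"]))
    deg_genes = {r.gene_id for r in ctx["degs"]}
    all_specific = {
        cell: spec[cell]["promoter"] | spec[cell]["enhancer"] for cell in spec
    }
    # scan every profiled element once per PWM; enrichment then contrasts a
    # cell's specific elements against all remaining profiled elements
    hits_by_tf = {
        pwm.tf_name: scan_elements(pwm, inp.sequences,
                                   score_fraction=cfg.score_fraction)
        for pwm in inp.pwms
    }
    all_elements = set(inp.sequences)
    enrich_rows = []
    significant: set[str] = set()
    for tf, hits in sorted(hits_by_tf.items()):
        hit_elements = {h.element_id for h in hits}
        for cell in (cfg.cell_b, cfg.cell_a):
            targets = all_specific[cell]
            k = len(hit_elements & targets)
            K = len(hit_elements)
            n, N = len(targets), len(all_elements)
            p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
            enrich_rows.append(dict(tf=tf, cell=cell, k=k, K=K, n=n, N=N, p=p))
            if p < cfg.motif_p:
                significant.add(tf)
    enrich = pd.DataFrame(enrich_rows)
    _write(enrich, out / "motif_enrichment.tsv")

    networks = {}
    edge_frames = []
    hub_rows = []
    for cell in (cfg.cell_a, cfg.cell_b):
        prom_hits = [
            h for tf in sorted(significant) for h in hits_by_tf[tf]
            if h.element_id in spec[cell]["promoter"]
        ]
        enh_hits = [
            h for tf in sorted(significant) for h in hits_by_tf[tf]
            if h.element_id in spec[cell]["enhancer"]
        ]
        net = build_network(prom_hits, enh_hits, gene_of, deg_genes,
                            restrict_tf_to_deg=True, cell=cell)
        networks[cell] = net
        edge_frames.append(net.edges)
        ji = jaccard_matrix(net)
        ji.rename_axis("tf").to_csv(out / f"jaccard_{cell}.tsv", sep="\t")
        for tf in hub_factors(ji, cfg.ji_min, cfg.min_partners):
            hub_rows.append(dict(cell=cell, tf=tf))
        ctx[f"jaccard_{cell}"] = ji
    ctx["networks"] = networks
    edges = pd.concat(edge_frames, ignore_index=True)
    _write(pd.DataFrame(hub_rows, columns=["cell", "tf"]), out / "hubs.tsv")
    return {"rows": _write(edges, out / "edges.tsv")}


def stage_cohort(cfg: RunConfig, inp: StudyInputs, ctx: dict, out: Path) -> dict:
    if inp.cohort_expression is None:
        ctx["cohort"] = None
        _write(pd.DataFrame(columns=["patient_id", "cluster"]), out / "clusters.tsv")
        return {"rows": 0}
    expr = inp.cohort_expression
    deg_genes = {r.gene_id for r in ctx["degs"]}
    panel = [g for g in expr.index if g in deg_genes] or list(expr.index)
    X = np.log2(expr.loc[panel].to_numpy(float) + 1.0)
    result = nmf_cluster(X, k=cfg.k, n_restarts=cfg.n_restarts, seed=cfg.seed)
    clusters = pd.DataFrame(
        {"patient_id": expr.columns, "cluster": result.cluster}
    )
    _write(clusters, out / "clusters.tsv")

    clin = inp.cohort_clinical.set_index("patient_id").loc[expr.columns]
    try:
        chi2, chi_p = contingency_chisq(result.cluster, clin["metastasis_label"])
    except ValueError:
        chi2, chi_p = float("nan"), float("nan")
    _write(
        pd.DataFrame([dict(test="cluster_vs_metastasis_chisq",
                           statistic=chi2, p=chi_p)]),
        out / "association.tsv",
    )
    ctx["cohort"] = dict(result=result, chi2=chi2, chi_p=chi_p)

    surv_rows = []
    times = clin["time"].to_numpy(float)
    events = clin["event"].to_numpy(int)
    for gene in panel:
        groups = split_by_mean(dict(zip(expr.columns, expr.loc[gene])))
        mask = np.array([groups[p] == "high" for p in expr.columns])
        if mask.all() or not mask.any():
            continue
        stat, p = logrank_test((times[mask], events[mask]),
                               (times[~mask], events[~mask]))
        surv_rows.append(dict(gene_id=gene, n_high=int(mask.sum()),
                              n_low=int((~mask).sum()), statistic=stat, p=p))
    surv = pd.DataFrame(surv_rows).sort_values(["p", "gene_id"]).reset_index(drop=True)
    ctx["survival_tests"] = surv
    _write(surv, out / "survival_tests.tsv")
    return {"rows": len(clusters)}


def stage_functional(cfg: RunConfig, inp: StudyInputs, ctx: dict, out: Path) -> dict:
    promoter_changed = {
        g for g in ctx["states_a"] if ctx["states_a"][g] != ctx["states_b"][g]
    }
    enhancer_changed = {
        c.nearest_gene for c in ctx["enhancer_calls"] if c.status != "stable"
    }
    deg_genes = {r.gene_id for r in ctx["degs"]}
    hallmarks = hallmark_percentages(
        inp.gene_sets, promoter_changed, enhancer_changed, deg_genes
    )
    _write(hallmarks, out / "hallmarks.tsv")
    universe = {g.gene_id for g in inp.genes} | deg_genes
    enrichment = geneset_enrichment(
        deg_genes & universe, inp.gene_sets, universe, cfg.max_fdr
    )
    ctx["hallmarks"] = hallmarks
    _write(enrichment, out / "geneset_enrichment.tsv")
    return {"rows": len(hallmarks)}


STAGES: list[tuple[str, Callable]] = [
    ("inputs", stage_inputs),
    ("profiles", stage_profiles),
    ("promoters", stage_promoters),
    ("enhancers", stage_enhancers),
    ("synergy", stage_synergy),
    ("superenhancers", stage_superenhancers),
    ("network", stage_network),
    ("cohort", stage_cohort),
    ("functional", stage_functional),
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage on ``cfg.data_dir``, writing outputs and a manifest.

    Returns the manifest dict (also written as ``manifest.json``).  Stages
    never rewrite another stage's outputs; any failure aborts the run with
    a :class:`StageError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(cfg.data_dir)
    ctx: dict = {}
    manifest: dict = {
        "config": json.loads(cfg.to_json()),
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }
    for name, fn in STAGES:
        before = {p.name for p in out.iterdir()}
        try:
            info = fn(cfg, inputs, ctx, out)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        new_files = sorted({p.name for p in out.iterdir()} - before)
        manifest["stages"][name] = {
            "rows": info.get("rows", 0),
            "outputs": {f: _sha256(out / f) for f in new_files},
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    ctx["manifest"] = manifest
    ctx["inputs"] = inputs
    return manifest
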