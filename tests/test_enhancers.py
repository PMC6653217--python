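"""Distal filtering, the Poisson differential test and synergy classes."""

import math

import numpy as np
import pytest
from scipy import stats

from cistro.enhancers import (
    call_distal_enhancers,
    classify_enhancer_changes,
    merge_intervals,
    nearest_gene,
    poisson_differential_test,
    synergy_table,
)
from cistro.io import ExpressionRecord, GeneModel, GenomicInterval, Peak


def _gene(gene_id, tss):
    return GeneModel(gene_id, tss, "+", GenomicInterval("chr1", tss, tss + 100, "+"))


def _peak(start, end, tags=100.0):
    return Peak(GenomicInterval("chr1", start, end), "H3K27ac", tags)


class TestDistalFilter:
    def test_far_peak_kept(self):
        kept = call_distal_enhancers([_peak(5_000, 5_500)], [_gene("G1", 1_000)])
        assert len(kept) == 1  # edge at 5000, TSS at 1000: distance 4000

    def test_peak_overlapping_tss_dropped(self):
        assert call_distal_enhancers([_peak(900, 1_500)], [_gene("G1", 1_000)]) == []

    def test_edge_exactly_at_threshold_kept(self):
        kept = call_distal_enhancers([_peak(3_000, 3_500)], [_gene("G1", 1_000)])
        assert len(kept) == 1  # 3000 - 1000 = 2000, >= rule

    def test_just_inside_threshold_dropped(self):
        assert call_distal_enhancers([_peak(2_999, 3_500)], [_gene("G1", 1_000)]) == []


class TestPoissonTest:
    def test_worked_example_against_pmf_summation(self):
        # scaled counts a=5, b=40: ratio 41/6, p = P(Pois(6) >= 40)
        ratio, p = poisson_differential_test(5, 40, 1e7, 1e7)
        assert 2.0**ratio == pytest.approx(41 / 6)
        direct = sum(
            math.exp(i * math.log(6.0) - 6.0 - math.lgamma(i + 1))
            for i in range(40, 200)
        )
        assert p == pytest.approx(direct, abs=1e-12)

    def test_equal_counts_symmetric(self):
        ratio, p = poisson_differential_test(17, 17, 1e7, 1e7)
        assert ratio == 0.0 and p >= 0.5

    def test_zero_zero_pseudocount_identity(self):
        ratio, p = poisson_differential_test(0, 0, 1e7, 1e7)
        assert ratio == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a, b = rng.integers(0, 500, size=2)
            la, lb = rng.uniform(5e6, 2e7, size=2)
            r1, p1 = poisson_differential_test(a, b, la, lb)
            r2, p2 = poisson_differential_test(b, a, lb, la)
            assert r1 == pytest.approx(-r2)
            assert p1 == pytest.approx(p2, abs=1e-15)

    def test_library_scaling(self):
        # identical concentration at different depths is not differential
        ratio, _p = poisson_differential_test(100, 200, 1e7, 2e7)
        assert abs(ratio) < 0.1

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            poisson_differential_test(-1, 5, 1e7, 1e7)


class TestMerge:
    def test_overlap_merge_and_gap_preserved(self):
        ivs = [
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 50, 150),
            GenomicInterval("chr1", 500, 600),
        ]
        merged = merge_intervals(ivs)
        assert [(m.start, m.end) for m in merged] == [(0, 150), (500, 600)]


class TestNearestGene:
    GENES = [_gene("G1", 1_000), _gene("G2", 20_000)]

    def test_basic(self):
        gene, dist = nearest_gene(GenomicInterval("chr1", 4_500, 5_500), self.GENES)
        assert gene == "G1" and dist == pytest.approx(3_999.5)

    def test_tie_lexicographic(self):
        mid = (1_000 + 20_000) / 2
        iv = GenomicInterval("chr1", int(mid), int(mid) + 1)
        assert nearest_gene(iv, self.GENES)[0] == "G1"

    def test_midpoint_at_tss(self):
        iv = GenomicInterval("chr1", 999, 1_002)  # midpoint 1000
        gene, dist = nearest_gene(iv, self.GENES)
        assert gene == "G1" and dist == 0.0

    def test_no_gene_on_chromosome(self):
        with pytest.raises(ValueError):
            nearest_gene(GenomicInterval("chrX", 0, 10), self.GENES)


class TestClassification:
    def test_thresholds(self):
        genes = [_gene("G1", 100_000)]
        a = [_peak(5_000, 6_000, tags=10)]
        b = [_peak(5_000, 6_000, tags=80)]
        (call,) = classify_enhancer_changes(a, b, 1e7, 1e7, genes)
        assert call.status == "gained"
        # threefold difference stays stable regardless of p
        b3 = [_peak(5_000, 6_000, tags=3_000)]
        a3 = [_peak(5_000, 6_000, tags=1_000)]
        (call,) = classify_enhancer_changes(a3, b3, 1e7, 1e7, genes)
        assert call.status == "stable"

    def test_statuses_partition_union(self, study, pipeline_run):
        _cfg, _inputs, ctx, _out = pipeline_run
        calls = ctx["enhancer_calls"]
        assert all(c.status in ("gained", "lost", "stable") for c in calls)
        ivs = sorted((c.interval.start, c.interval.end) for c in calls)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2  # regions are disjoint

    def test_swapping_cells_maps_gained_to_lost(self, study):
        cfg = study.cfg
        a = study.peaks[(cfg.cell_a, "H3K27ac")]
        b = study.peaks[(cfg.cell_b, "H3K27ac")]
        lib = cfg.depth_per_cell
        fwd = classify_enhancer_changes(a, b, lib, lib, study.genes)
        rev = classify_enhancer_changes(b, a, lib, lib, study.genes)
        flip = {"gained": "lost", "lost": "gained", "stable": "stable"}
        assert [c.status for c in rev] == [flip[c.status] for c in fwd]
        np.testing.assert_allclose(
            [c.p_value for c in rev], [c.p_value for c in fwd], atol=1e-300
        )

    def test_gained_genes_more_upregulated_than_lost(self, study, pipeline_run):
        _cfg, _inputs, ctx, _out = pipeline_run
        calls = ctx["enhancer_calls"]
        fc = {r.gene_id: np.log2(r.fc) for r in study.expression}
        gained = [fc[c.nearest_gene] for c in calls if c.status == "gained"
                  and c.nearest_gene in fc]
        lost = [fc[c.nearest_gene] for c in calls if c.status == "lost"
                and c.nearest_gene in fc]
        assert np.mean(gained) > np.mean(lost)


class TestSynergy:
    DEGS = [
        ExpressionRecord("G1", 1, 16, 16.0, 1e-4, True, "up"),
        ExpressionRecord("G2", 16, 1, 1 / 16, 1e-4, True, "down"),
        ExpressionRecord("G3", 1, 8, 8.0, 1e-4, True, "up"),
    ]

    def test_labels_and_none_status(self):
        transitions = {
            "G1": ("Repressive", "Active"),
            "G2": ("Active", "Repressive"),
            "G3": ("None", "Active"),
        }
        from cistro.enhancers import EnhancerCall

        calls = [
            EnhancerCall(GenomicInterval("chr1", 5_000, 6_000), 5, 80, 4.0, 1e-9,
                         "gained", "G1", 4_000),
        ]
        table, means = synergy_table(transitions, calls, self.DEGS)
        row = table.set_index("gene_id")
        assert row.loc["G1", "label"] == "P-activated & E-gained"
        assert row.loc["G2", "label"] == "P-repressed & E-none"
        assert row.loc["G3", "enhancer_status"] == "none"
        assert means["P-activated & E-gained"] == pytest.approx(4.0)

    def test_additive_enhancer_effect_on_synthetic_data(self, pipeline_run):
        """Activated promoter plus gained enhancer shifts expression above
        activated promoter alone."""
        _cfg, _inputs, ctx, _out = pipeline_run
        table = ctx["synergy"]
        both = table[(table["label"] == "P-activated & E-gained")]["log2fc"]
        prom_only = table[(table["label"] == "P-activated & E-none")]["log2fc"]
        assert len(both) and len(prom_only)
        assert both.mean() > prom_only.mean()
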