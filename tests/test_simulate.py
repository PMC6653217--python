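"""Generator determinism, construction guarantees and truth consistency."""

import numpy as np
import pytest

from cistro.simulate import (
    SimulationConfig,
    audit_consistency,
    make_synthetic_pwms,
    planted_log2fc,
    simulate_chromatin,
    simulate_cohort,
    simulate_expression,
    simulate_genome,
    simulate_sequences_with_motifs,
    simulate_study,
    _element_table,
    _motif_target_pool,
)


def _cfg(**kw):
    return SimulationConfig(**{"seed": 5, "n_genes": 60, **kw})


class TestGenome:
    def test_spacing_guarantee(self):
        cfg = _cfg()
        genes, sizes = simulate_genome(cfg)
        tss = sorted(g.tss for g in genes)
        gaps = np.diff(tss)
        assert gaps.min() >= cfg.min_spacing_bp
        assert max(g.tss for g in genes) + 3_000 < sizes[cfg.chrom]

    def test_determinism(self):
        a, _ = simulate_genome(_cfg())
        b, _ = simulate_genome(_cfg())
        assert a == b

    def test_infeasible_spacing_errors(self):
        with pytest.raises(ValueError, match="spacing"):
            SimulationConfig(seed=0, n_genes=100, chrom_length_bp=1_000_000).validate()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            _cfg(n_genes=5).validate()
        with pytest.raises(ValueError):
            _cfg(enhancer_gain_rate=1.5).validate()
        bad = _cfg()
        bad.state_transition_probs = {("Active", "Active"): 0.5}
        with pytest.raises(ValueError, match="sum to 1"):
            bad.validate()


class TestChromatin:
    def test_state_construction_rules(self):
        cfg = _cfg()
        genes, _ = simulate_genome(cfg)
        peaks, truth = simulate_chromatin(cfg, genes)
        marked = {
            (cell, mark): {
                p.name.split(":", 1)[1]
                for p in plist if p.name.startswith("prom:")
            }
            for (cell, mark), plist in peaks.items()
        }
        for gene, (state_a, state_b) in truth.states.items():
            for cell, state in ((cfg.cell_a, state_a), (cfg.cell_b, state_b)):
                has_k4 = gene in marked[(cell, "H3K4me3")]
                has_k27me3 = gene in marked[(cell, "H3K27me3")]
                assert has_k4 == (state in ("Active", "Poised"))
                assert has_k27me3 == (state in ("Repressive", "Poised"))

    def test_gained_enhancer_intensity_ratio(self):
        cfg = _cfg()
        genes, _ = simulate_genome(cfg)
        _, truth = simulate_chromatin(cfg, genes)
        gained = [e for e in truth.enhancers if e.status == "gained" and e.se_id is None]
        assert gained, "expected at least one gained enhancer"
        for e in gained:
            assert e.intensity_b / e.intensity_a == pytest.approx(cfg.enhancer_true_fold)

    def test_every_peak_maps_to_truth_when_noise_off(self, study):
        assert audit_consistency(study) == []

    def test_super_enhancer_loci_are_clustered(self, study):
        cfg = study.cfg
        for se_id, span, _gene, _status in study.truth.se_regions:
            members = [e for e in study.truth.enhancers if e.se_id == se_id]
            assert len(members) >= cfg.se_n_constituents
            starts = sorted(m.interval.start for m in members)
            assert all(b - a <= 12_500 for a, b in zip(starts, starts[1:]))
            assert span.length <= 12_500 * len(members)


class TestExpression:
    def test_noise_free_fold_change_is_exact(self):
        cfg = _cfg()
        genes, _ = simulate_genome(cfg)
        _, truth = simulate_chromatin(cfg, genes)
        records = {r.gene_id: r for r in simulate_expression(cfg, truth, noise_sd=0.0)}
        for gene, (sa, sb) in truth.states.items():
            expected = planted_log2fc(cfg, truth, gene)
            assert np.log2(records[gene].fc) == pytest.approx(expected, abs=1e-9)

    def test_repressive_to_active_with_effect_three_gives_fc_eight(self):
        cfg = _cfg()
        cfg.effect_log2fc_by_transition = {("Repressive", "Active"): 3.0}
        cfg.state_transition_probs = {("Repressive", "Active"): 1.0}
        cfg.enhancer_rate = 0.0
        cfg.se_fraction = 0.0
        genes, _ = simulate_genome(cfg)
        _, truth = simulate_chromatin(cfg, genes)
        records = simulate_expression(cfg, truth, noise_sd=0.0)
        for r in records[: cfg.n_genes]:
            assert r.fc == pytest.approx(8.0)

    def test_class_mean_obeys_clt_bound(self):
        cfg = SimulationConfig(seed=9, n_genes=200)
        cfg.state_transition_probs = {("None", "Active"): 1.0}
        cfg.effect_log2fc_by_transition = {("None", "Active"): 2.0}
        cfg.enhancer_rate = 0.0
        cfg.se_fraction = 0.0
        genes, _ = simulate_genome(cfg)
        _, truth = simulate_chromatin(cfg, genes)
        records = simulate_expression(cfg, truth)
        log2fc = np.log2([r.fc for r in records[: cfg.n_genes]])
        bound = 3 * cfg.noise_sd / np.sqrt(cfg.n_genes)
        assert abs(log2fc.mean() - 2.0) <= bound


class TestMotifs:
    def test_pwms_distinct_and_high_information(self):
        cfg = _cfg()
        pwms = make_synthetic_pwms(cfg)
        consensi = [p.consensus for p in pwms]
        assert len(set(consensi)) == len(consensi)
        for p in pwms:
            assert p.matrix.max(axis=1).min() == cfg.pwm_consensus_prob

    def test_planted_consensus_present(self, study):
        for tf, eid, offset in study.truth.tf_element_hits:
            pwm = next(p for p in study.pwms if p.tf_name == tf)
            assert study.sequences[eid][offset:offset + pwm.width] == pwm.consensus

    def test_cooccurrence_prob_one_pairs_every_element(self):
        cfg = _cfg(motif_cooccurrence_prob=1.0, targets_per_tf=10, n_tfs=2)
        genes, _ = simulate_genome(cfg)
        _, truth = simulate_chromatin(cfg, genes)
        pwms = make_synthetic_pwms(cfg)
        elements = _element_table(cfg, genes, truth)
        simulate_sequences_with_motifs(
            cfg, elements, pwms, truth, _motif_target_pool(truth)
        )
        by_tf: dict[str, set[str]] = {}
        for tf, eid, _ in truth.tf_element_hits:
            by_tf.setdefault(tf, set()).add(eid)
        assert by_tf["TF01"] == by_tf["TF02"]


class TestCohort:
    def test_marker_shift_and_groups(self):
        cfg = _cfg(n_patients=300)
        expr, clinical, groups = simulate_cohort(cfg, ["M1", "M2"], ["N1"])
        g = np.array([groups[p] for p in expr.columns])
        marker_mean = np.log2(expr.loc["M1"]).groupby(g).mean()
        assert marker_mean[2] - marker_mean[1] == pytest.approx(
            cfg.marker_delta_log2, abs=0.5
        )
        null_mean = np.log2(expr.loc["N1"]).groupby(g).mean()
        assert abs(null_mean[2] - null_mean[1]) < 0.5
        assert clinical["event"].isin((0, 1)).all()
        assert (clinical["time"] >= 0).all()

    def test_requires_marker_gene(self):
        with pytest.raises(ValueError):
            simulate_cohort(_cfg(), [])


class TestStudy:
    def test_full_determinism(self):
        a = simulate_study(_cfg())
        b = simulate_study(_cfg())
        assert [r.fc for r in a.expression] == [r.fc for r in b.expression]
        assert a.sequences == b.sequences
        assert a.cohort_clinical.equals(b.cohort_clinical)
        for key in a.peaks:
            assert [p.tag_count for p in a.peaks[key]] == [
                p.tag_count for p in b.peaks[key]
            ]

    def test_artifacts_parse_back(self, study, study_dir):
        from cistro.pipeline import load_inputs

        inputs = load_inputs(study_dir)
        assert len(inputs.genes) == study.cfg.n_genes
        assert set(inputs.sequences) == set(study.sequences)
        assert len(inputs.expression) == len(study.expression)
        assert inputs.cohort_expression.shape == study.cohort_expression.shape
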