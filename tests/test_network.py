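"""PWM scanning, motif enrichment, network building and cooperation scores."""

import itertools

import numpy as np
import pytest

from cistro.io import Pwm
from cistro.network import (
    MotifHit,
    RegulatoryNetwork,
    build_network,
    hub_factors,
    jaccard_matrix,
    max_score,
    motif_enrichment,
    scan_elements,
    scan_pwm,
)

_BASES = "ACGT"
_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _pwm(consensus: str, p: float = 0.85, name: str = "TF1") -> Pwm:
    off = (1 - p) / 3
    m = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        m[i, _BASES.index(b)] = p
    return Pwm(name, m)


def _revcomp(s: str) -> str:
    return "".join(_RC[b] for b in reversed(s))


class TestScanner:
    def test_consensus_scores_max_and_hits(self):
        pwm = _pwm("ACGTAC")
        seq = "TTTTT" + "ACGTAC" + "TTTTT"
        hits = scan_pwm(pwm, seq)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and fwd[0].offset == 5
        assert fwd[0].score == pytest.approx(max_score(pwm))

    def test_reverse_complement_same_score_minus_strand(self):
        pwm = _pwm("ACGTAC")
        seq = "TTTTT" + _revcomp("ACGTAC") + "TTTTT"
        hits = [h for h in scan_pwm(pwm, seq) if h.strand == "-"]
        assert len(hits) == 1 and hits[0].offset == 5
        assert hits[0].score == pytest.approx(max_score(pwm))

    def test_strand_symmetry_on_revcomped_sequence(self):
        rng = np.random.default_rng(2)
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, 500))
        pwm = _pwm("ACGGTACC")
        fwd = scan_pwm(pwm, seq)
        rev = scan_pwm(pwm, _revcomp(seq))
        mirrored = sorted(
            (len(seq) - pwm.width - h.offset, {"+": "-", "-": "+"}[h.strand],
             round(h.score, 9))
            for h in rev
        )
        assert mirrored == sorted((h.offset, h.strand, round(h.score, 9)) for h in fwd)

    def test_n_windows_skipped(self):
        pwm = _pwm("ACGTAC")
        assert scan_pwm(pwm, "ACGNAC") == []

    def test_pwm_wider_than_sequence(self):
        assert scan_pwm(_pwm("ACGTACGT"), "ACG") == []

    def test_hit_rate_matches_exhaustive_word_enumeration(self):
        """Hits on a long random sequence are exactly the offsets whose word
        (or reverse complement) is in the enumerated above-threshold set."""
        pwm = _pwm("ACGTC", p=0.7)
        lo = np.log2(pwm.matrix / 0.25)
        threshold = 0.8 * max_score(pwm)
        hit_words = {
            "".join(w)
            for w in itertools.product(_BASES, repeat=5)
            if sum(lo[i, _BASES.index(b)] for i, b in enumerate(w)) >= threshold
        }
        rng = np.random.default_rng(7)
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, 20_000))
        expected = set()
        for off in range(len(seq) - 4):
            word = seq[off:off + 5]
            if word in hit_words:
                expected.add((off, "+"))
            if _revcomp(word) in hit_words:
                expected.add((off, "-"))
        got = {(h.offset, h.strand) for h in scan_pwm(pwm, seq)}
        assert got == expected

    def test_scan_elements_matches_per_sequence_scan(self):
        rng = np.random.default_rng(3)
        seqs = {
            f"E{i}": "".join(_BASES[j] for j in rng.integers(0, 4, 300))
            for i in range(20)
        }
        pwm = _pwm("ACGTACG", p=0.6)
        batched = {(h.element_id, h.offset, h.strand)
                   for h in scan_elements(pwm, seqs)}
        single = {
            (e, h.offset, h.strand)
            for e, s in seqs.items()
            for h in scan_pwm(pwm, s, e)
        }
        assert batched == single


class TestEnrichment:
    def test_exact_combinatorial_value(self):
        # N=10, n=5, K=4, k=4 -> C(4,4) C(6,1) / C(10,5) = 6/252
        pwm = _pwm("ACGTACGT")
        targets = {f"T{i}": "ACGTACGT" + "T" * 20 for i in range(4)}
        targets["T4"] = "T" * 28
        background = {f"B{i}": "T" * 28 for i in range(5)}
        p = motif_enrichment(pwm, targets, background)
        assert p == pytest.approx(6 / 252)

    def test_no_hits_p_one(self):
        pwm = _pwm("ACGTACGT")
        p = motif_enrichment(pwm, {"T": "T" * 30}, {"B": "T" * 30})
        assert p == 1.0

    def test_all_elements_hit_p_one(self):
        pwm = _pwm("ACGTACGT")
        p = motif_enrichment(
            pwm, {"T": "ACGTACGT"}, {"B": "ACGTACGT"}
        )
        assert p == 1.0

    def test_overlapping_sets_rejected(self):
        pwm = _pwm("ACGT")
        with pytest.raises(ValueError):
            motif_enrichment(pwm, {"X": "ACGT"}, {"X": "ACGT"})

    def test_matches_exact_oracle_on_small_configurations(self):
        """Hypergeometric tail equals the exact combinatorial sum for all
        N <= 12 configurations."""
        from math import comb

        from scipy import stats

        for N in range(1, 13):
            for n in range(0, N + 1):
                for K in range(0, N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        exact = sum(
                            comb(K, j) * comb(N - K, n - j)
                            for j in range(k, min(n, K) + 1)
                        ) / comb(N, n)
                        assert stats.hypergeom.sf(k - 1, N, K, n) == pytest.approx(
                            exact, abs=1e-12
                        )


def _net(edges):
    import pandas as pd

    rows = [dict(tf=t, target=g, mode="proximal", cell="X") for t, g in edges]
    return RegulatoryNetwork(
        pd.DataFrame(rows, columns=["tf", "target", "mode", "cell"]), "X"
    )


class TestNetwork:
    def test_promoter_hit_gives_proximal_edge(self):
        net = build_network(
            [MotifHit("TF1", "PROM_G1", 0, "+", 9.9)], [],
            {"PROM_G1": "G1"}, restrict_tf_to_deg=False,
        )
        assert net.edges.iloc[0].tolist() == ["TF1", "G1", "proximal", ""]

    def test_both_modes_collapse(self):
        net = build_network(
            [MotifHit("TF1", "PROM_G1", 0, "+", 9.9)],
            [MotifHit("TF1", "ENH_1", 3, "-", 9.9)],
            {"PROM_G1": "G1", "ENH_1": "G1"},
            restrict_tf_to_deg=False,
        )
        assert len(net.edges) == 1 and net.edges.iloc[0]["mode"] == "both"

    def test_deg_restriction(self):
        hits = [MotifHit("TF1", "PROM_G1", 0, "+", 9.9)]
        net = build_network(hits, [], {"PROM_G1": "G1"}, deg_genes={"OTHER"})
        assert len(net.edges) == 0

    def test_unassigned_element_warns_and_skips(self):
        with pytest.warns(UserWarning, match="no gene assignment"):
            net = build_network(
                [MotifHit("TF1", "MYSTERY", 0, "+", 9.9)], [], {},
                restrict_tf_to_deg=False,
            )
        assert len(net.edges) == 0


class TestJaccard:
    def test_worked_example(self):
        net = _net([("A", "g1"), ("A", "g2"), ("A", "g3"),
                    ("B", "g2"), ("B", "g3"), ("B", "g4")])
        m = jaccard_matrix(net)
        assert m.loc["A", "B"] == pytest.approx(0.5)
        assert m.loc["A", "A"] == 1.0

    def test_identical_and_disjoint(self):
        net = _net([("A", "g1"), ("B", "g1"), ("C", "g9")])
        m = jaccard_matrix(net)
        assert m.loc["A", "B"] == 1.0
        assert m.loc["A", "C"] == 0.0

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n_tf, n_gene = int(rng.integers(2, 8)), int(rng.integers(2, 15))
            edges = {
                (f"T{t}", f"g{g}")
                for t in range(n_tf)
                for g in range(n_gene)
                if rng.random() < 0.3
            }
            if not edges:
                continue
            net = _net(sorted(edges))
            m = jaccard_matrix(net)
            sets: dict[str, set] = {}
            for t, g in edges:
                sets.setdefault(t, set()).add(g)
            for a in m.index:
                for b in m.columns:
                    expect = len(sets[a] & sets[b]) / len(sets[a] | sets[b])
                    assert m.loc[a, b] == expect

    def test_symmetry_and_range(self, pipeline_run):
        _cfg, _inputs, ctx, _out = pipeline_run
        m = ctx["jaccard_LM2_4175"]
        assert np.allclose(m.values, m.values.T)
        assert ((m.values >= 0) & (m.values <= 1)).all()
        assert np.allclose(np.diag(m.values), 1.0)


class TestHubs:
    def _matrix(self, n_partners, ji):
        import pandas as pd

        tfs = ["HUB"] + [f"P{i}" for i in range(n_partners)]
        m = pd.DataFrame(0.0, index=tfs, columns=tfs)
        np.fill_diagonal(m.values, 1.0)
        for p in tfs[1:]:
            m.loc["HUB", p] = m.loc[p, "HUB"] = ji
        return m

    def test_eleven_partners_above_threshold_is_hub(self):
        assert hub_factors(self._matrix(11, 0.4)) == ["HUB"]

    def test_ten_partners_not_hub(self):
        assert hub_factors(self._matrix(10, 0.4)) == []

    def test_ji_exactly_at_threshold_not_counted(self):
        assert hub_factors(self._matrix(20, 0.3)) == []
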