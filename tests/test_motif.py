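import itertools

import numpy as np
import pytest

from cnegrn.motif import (MotifModel, _Scanner, aggregate_B, motif_enrichment,
                          read_hit_table, read_motifs, scan, scan_regions,
                          score_distribution, write_jaspar)


def _consensus_motif(consensus, strength=0.97, name="m"):
    w = len(consensus)
    counts = np.full((4, w), (1 - strength) / 3 * 100)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = strength * 100
    return MotifModel(name, counts)


JASPAR_ONE = """>MA0001.1 test1
A [ 10 2 0 30 ]
C [ 5 20 1 0 ]
G [ 5 3 30 0 ]
T [ 10 5 0 0 ]
"""

MEME_THREE = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF alpha
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0
0.80 0.05 0.05 0.10
0.10 0.70 0.10 0.10
0.05 0.05 0.85 0.05
0.25 0.25 0.25 0.25

MOTIF beta
letter-probability matrix: alength= 4 w= 5 nsites= 20 E= 0
0.97 0.01 0.01 0.01
0.01 0.97 0.01 0.01
0.01 0.01 0.97 0.01
0.01 0.01 0.01 0.97
0.25 0.25 0.25 0.25

MOTIF gamma
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0
0.25 0.25 0.25 0.25
0.97 0.01 0.01 0.01
0.01 0.97 0.01 0.01
0.25 0.25 0.25 0.25
"""


class TestReadWrite:
    def test_jaspar_single(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(JASPAR_ONE)
        models = read_motifs(str(p), "JASPAR")
        assert len(models) == 1 and models[0].width == 4

    def test_meme_minimal_three(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(MEME_THREE)
        models = read_motifs(str(p), "MEME")
        assert [m.name for m in models] == ["alpha", "beta", "gamma"]
        assert [m.width for m in models] == [4, 5, 4]

    def test_round_trip_preserves_matrix(self, tmp_path):
        m = _consensus_motif("TGACTCA")
        write_jaspar([m], str(tmp_path / "rt.jaspar"))
        back = read_motifs(str(tmp_path / "rt.jaspar"), "JASPAR")[0]
        assert np.allclose(back.counts, m.counts, atol=1e-9)
        assert np.allclose(back.pfm, m.pfm, atol=1e-9)

    def test_zero_sum_column_rejected(self):
        counts = np.ones((4, 4))
        counts[:, 2] = 0
        with pytest.raises(ValueError, match="zero-sum"):
            MotifModel("bad", counts)


class TestScan:
    def test_consensus_match_position_and_strand(self):
        m = _consensus_motif("TAAT")
        hits = scan("GGTAATGG", m, p_threshold=1e-2)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1 and plus[0].position == 2

    def test_no_hits_below_threshold(self):
        m = _consensus_motif("TAATTAAT")
        assert scan("GGGGCCCCGGGGCCCC", m, p_threshold=1e-4) == []

    def test_short_sequence_empty(self):
        assert scan("TA", _consensus_motif("TAAT")) == []

    def test_n_windows_skipped(self):
        m = _consensus_motif("TAAT")
        assert scan("GGTANTGG", m, p_threshold=1e-2) == []

    def test_reverse_strand_hit(self):
        m = _consensus_motif("TTAC")          # revcomp GTAA
        hits = scan("GGGTAAGG", m, p_threshold=1e-2)
        assert any(h.strand == "-" for h in hits)

    def test_pmf_sums_to_one_and_p_monotone(self):
        rng = np.random.default_rng(0)
        m = MotifModel("r", rng.uniform(0.5, 20, (4, 6)))
        pmf, _, _ = score_distribution(m)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
        sc = _Scanner(m)
        lo, hi = sc.min_sum, sc.min_sum + len(sc.survival) - 1
        grid = np.linspace(lo, hi, 50).astype(int)
        ps = [sc.p_value(int(s)) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("width", [4, 6, 8])
    def test_exact_p_equals_enumeration_oracle(self, width):
        """DP tail probabilities equal exhaustive enumeration of all 4^w
        windows under the background, on the shared integer grid."""
        rng = np.random.default_rng(width)
        m = MotifModel("r", rng.uniform(0.5, 20, (4, width)),
                       background=np.array([0.3, 0.2, 0.2, 0.3]))
        sc = _Scanner(m)
        int_m = np.rint(m.log_odds * sc.scale).astype(np.int64)
        scores, probs = [], []
        for word in itertools.product(range(4), repeat=width):
            scores.append(sum(int_m[b, j] for j, b in enumerate(word)))
            probs.append(np.prod([m.background[b] for b in word]))
        scores, probs = np.array(scores), np.array(probs)
        for s in np.unique(scores)[:: max(1, len(np.unique(scores)) // 40)]:
            expected = probs[scores >= s].sum()
            assert sc.p_value(int(s)) == pytest.approx(expected, rel=1e-9)


class TestAggregate:
    def test_neglog_sum(self):
        out = aggregate_B([("r1", "tf", 0.01), ("r1", "tf", 0.001)])
        assert len(out) == 1
        assert out.loc[0, "B"] == pytest.approx(5.0)
        assert out.loc[0, "n_hits"] == 2

    def test_no_hits_absent(self):
        assert len(aggregate_B([])) == 0

    def test_additivity_under_concatenation(self):
        rng = np.random.default_rng(1)
        a = [("r", "t", float(p)) for p in rng.uniform(1e-6, 1, 5)]
        b = [("r", "t", float(p)) for p in rng.uniform(1e-6, 1, 7)]
        merged = aggregate_B(a + b).loc[0, "B"]
        assert merged == pytest.approx(aggregate_B(a).loc[0, "B"]
                                       + aggregate_B(b).loc[0, "B"])

    def test_zero_p_capped(self):
        out = aggregate_B([("r", "t", 0.0)], cap=10.0)
        assert out.loc[0, "B"] == 10.0


class TestHitTableIO:
    def test_per_match_aggregated(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("region_id\ttf\tneglog10p\nr1\ta\t2\nr1\ta\t3\n")
        out = read_hit_table(str(p))
        assert len(out) == 1 and out.loc[0, "B"] == pytest.approx(5.0)

    def test_pre_aggregated_passthrough(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("region_id\ttf\tB\nr1\ta\t4.28486\n")
        out = read_hit_table(str(p))
        assert out.loc[0, "B"] == pytest.approx(4.28486)

    def test_mixed_schema_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("region_id\ttf\tneglog10p\tB\nr1\ta\t2\t2\n")
        with pytest.raises(ValueError, match="mixed"):
            read_hit_table(str(p))

    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("region_id\ttf\tneglog10p\n")
        assert len(read_hit_table(str(p))) == 0


def _hyper_oracle(k, N, K, n):
    """Upper-tail hypergeometric by direct pmf enumeration."""
    from math import comb
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)
               ) / comb(N, n)


class TestEnrichment:
    def _table(self, pairs):
        return aggregate_B([(r, t, 0.001) for r, t in pairs])

    def test_hypergeometric_matches_enumeration(self):
        target = [f"t{i}" for i in range(10)]
        background = [f"b{i}" for i in range(90)]
        pairs = [(r, "tf") for r in target[:5]] + \
                [(r, "tf") for r in background[:5]]
        out = motif_enrichment(target, background, self._table(pairs))
        assert out.loc[0, "p"] == pytest.approx(
            _hyper_oracle(5, 100, 10, 10), rel=1e-9)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(2)
        universe = [f"r{i}" for i in range(200)]
        for _ in range(10):
            target = list(rng.choice(universe, 30, replace=False))
            background = [r for r in universe if r not in target]
            bearing = rng.choice(universe, 40, replace=False)
            out = motif_enrichment(target, background,
                                   self._table([(r, "tf") for r in bearing]))
            k = len(set(bearing) & set(target))
            assert out.loc[0, "p"] == pytest.approx(
                _hyper_oracle(k, 200, 40, 30), rel=1e-9)

    def test_null_composition(self):
        target = [f"t{i}" for i in range(10)]
        background = [f"b{i}" for i in range(90)]
        pairs = [(r, "tf") for r in target[:2]] + \
                [(r, "tf") for r in background[:18]]  # same 20% rate
        out = motif_enrichment(target, background, self._table(pairs))
        assert out.loc[0, "fold"] == pytest.approx(1.0)
        assert out.loc[0, "p"] >= 0.5

    def test_extreme_case_minimal_p(self):
        target = [f"t{i}" for i in range(5)]
        background = [f"b{i}" for i in range(95)]
        out = motif_enrichment(target, background,
                               self._table([(r, "tf") for r in target]))
        assert out.loc[0, "p"] == pytest.approx(
            _hyper_oracle(5, 100, 5, 5), rel=1e-9)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment([], ["b"], self._table([("b", "t")]))


class TestScanRegions:
    def test_matches_single_scan(self):
        m1, m2 = _consensus_motif("TAATGA", name="a"), \
            _consensus_motif("CCGATC", name="b")
        rng = np.random.default_rng(3)
        seqs = {}
        for i in range(5):
            s = "".join(rng.choice(list("ACGT"), 60))
            seqs[f"r{i}"] = s[:20] + "TAATGA" + s[26:]
        recs = scan_regions(seqs, [m1, m2], p_threshold=1e-3)
        for rid, seq in seqs.items():
            for m in (m1, m2):
                expected = sorted(h.p for h in scan(seq, m, p_threshold=1e-3))
                got = sorted(p for r, t, p in recs
                             if r == rid and t == m.name)
                assert np.allclose(got, expected)
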