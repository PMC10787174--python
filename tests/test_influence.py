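import numpy as np
import pandas as pd
import pytest

from cnegrn.influence import (functional_influence, influence_table,
                              rank_within_type, regulatory_strength,
                              regulatory_strength_t)
from cnegrn.motif import aggregate_B


def _network(triplets, gammas):
    return pd.DataFrame(
        [(t, c, g, gam, True) for (t, c, g), gam in zip(triplets, gammas)],
        columns=["ttf", "cne", "target", "gamma", "retained"])


def _b_table(pairs_b):
    return pd.DataFrame([(r, t, b, 1) for (r, t), b in pairs_b.items()],
                        columns=["region_id", "tf", "B", "n_hits"])


class TestRegulatoryStrengthT:
    def _single(self, gamma_transform="power2", gamma=1.0):
        samples = ["s1"]
        net = _network([("HOXC8", "K", "SLC14A1")], [gamma])
        opn = pd.DataFrame({"s1": [18.83]}, index=["K"])
        b = _b_table({("K", "HOXC8"): 4.28486})
        ttf = pd.DataFrame({"s1": [25.48]}, index=["HOXC8"])
        tgt = pd.DataFrame({"s1": [42.34]}, index=["SLC14A1"])
        return regulatory_strength_t("K", samples, net, opn, b, ttf, tgt,
                                     gamma_transform)

    def test_single_triplet_product(self):
        # direct arithmetic oracle on realistic magnitudes
        expected = 18.83 * 4.28486 * 25.48 * 42.34 * 2.0 ** 1.0
        assert self._single() == pytest.approx(expected, rel=1e-12)

    def test_linear_gamma_flag(self):
        expected = 18.83 * 4.28486 * 25.48 * 42.34 * 2.0 * 1.0
        assert self._single("linear2") == pytest.approx(expected, rel=1e-12)

    def test_no_triplets_zero(self):
        net = _network([("T", "other", "G")], [0.9])
        out = regulatory_strength_t("K", ["s1"], net,
                                    pd.DataFrame({"s1": [1.0]}, index=["K"]),
                                    _b_table({}),
                                    pd.DataFrame({"s1": [1.0]}, index=["T"]),
                                    pd.DataFrame({"s1": [1.0]}, index=["G"]))
        assert out == 0.0

    def test_linear_in_openness(self):
        samples = ["s1"]
        net = _network([("T", "K", "G")], [0.8])
        b = _b_table({("K", "T"): 2.0})
        ttf = pd.DataFrame({"s1": [3.0]}, index=["T"])
        tgt = pd.DataFrame({"s1": [7.0]}, index=["G"])
        r1 = regulatory_strength_t("K", samples, net,
                                   pd.DataFrame({"s1": [2.0]}, index=["K"]),
                                   b, ttf, tgt)
        r2 = regulatory_strength_t("K", samples, net,
                                   pd.DataFrame({"s1": [4.0]}, index=["K"]),
                                   b, ttf, tgt)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_missing_binding_strength_raises(self):
        net = _network([("T", "K", "G")], [0.8])
        with pytest.raises(KeyError, match="inconsistent"):
            regulatory_strength_t(
                "K", ["s1"], net,
                pd.DataFrame({"s1": [1.0]}, index=["K"]), _b_table({}),
                pd.DataFrame({"s1": [1.0]}, index=["T"]),
                pd.DataFrame({"s1": [1.0]}, index=["G"]))

    def test_naive_summation_oracle_random_networks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n_trip = int(rng.integers(1, 21))
            ttfs = [f"T{i}" for i in range(3)]
            tgts = [f"G{i}" for i in range(5)]
            samples = ["s1", "s2"]
            trips = [(ttfs[rng.integers(3)], "K", tgts[rng.integers(5)])
                     for _ in range(n_trip)]
            gammas = rng.uniform(0.7, 1.0, n_trip)
            net = _network(trips, gammas)
            opn = pd.DataFrame([rng.uniform(1, 20, 2)], index=["K"],
                               columns=samples)
            b = _b_table({("K", t): float(rng.uniform(1, 5)) for t in ttfs})
            ttf = pd.DataFrame(rng.uniform(1, 50, (3, 2)), index=ttfs,
                               columns=samples)
            tgt = pd.DataFrame(rng.uniform(1, 50, (5, 2)), index=tgts,
                               columns=samples)
            got = regulatory_strength_t("K", samples, net, opn, b, ttf, tgt)
            o_mean = opn.loc["K"].mean()
            expected = sum(
                o_mean * b.set_index(["region_id", "tf"]).loc[("K", t), "B"]
                * ttf.loc[t].mean() * tgt.loc[g].mean() * 2.0 ** gam
                for (t, _, g), gam in zip(trips, gammas))
            assert got == pytest.approx(expected, rel=1e-12)


class TestAggregation:
    def test_max_over_time(self):
        assert regulatory_strength({"E60": 1.0, "D1": 5.0, "D7": 3.0}) == 5.0
        assert regulatory_strength({"E60": 2.0}) == 2.0
        assert regulatory_strength({"E60": 0.0, "D1": 0.0}) == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            regulatory_strength({})

    def test_geometric_mean(self):
        assert functional_influence(4.0, 9.0) == pytest.approx(6.0, abs=1e-12)
        assert functional_influence(0.0, 5.0) == 0.0
        # homogeneity: scaling R by 4 scales W by 2
        w1 = functional_influence(3.0, 7.0)
        assert functional_influence(12.0, 7.0) == pytest.approx(2 * w1,
                                                                rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            functional_influence(-1.0, 1.0)


class TestRanking:
    def _records(self):
        return pd.DataFrame(
            [("a", "II", 10.0, 0.5, 10.0), ("b", "II", 5.0, 0.5, 5.0),
             ("c", "I", 100.0, 0.9, 100.0), ("d", "II", 5.0, 0.5, 5.0)],
            columns=["cne_id", "type", "R", "C", "W"])

    def test_within_type_ranks(self):
        out = rank_within_type(self._records()).set_index("cne_id")
        assert out.loc["a", "rank_within_type"] == 1
        assert out.loc["b", "rank_within_type"] == 2
        assert out.loc["c", "rank_within_type"] == 1   # sole type I

    def test_types_do_not_interact(self):
        base = rank_within_type(self._records()).set_index("cne_id")
        no_type_i = rank_within_type(
            self._records().query("type == 'II'")).set_index("cne_id")
        for cid in ("a", "b", "d"):
            assert base.loc[cid, "rank_within_type"] == \
                no_type_i.loc[cid, "rank_within_type"]

    def test_ties_share_rank_listed_by_id(self):
        out = rank_within_type(self._records())
        tied = out[out["cne_id"].isin(["b", "d"])]
        assert set(tied["rank_within_type"]) == {2}
        assert tied["cne_id"].tolist() == ["b", "d"]

    def test_monotone_in_r_and_c(self):
        w = functional_influence
        assert w(2, 3) < w(4, 3) < w(4, 5)

    def test_within_type_rank_invariant_under_c_scaling(self):
        rec = self._records()
        scaled = rec.copy()
        scaled.loc[scaled["type"] == "II", "C"] *= 7.0
        scaled["W"] = np.sqrt(scaled["R"] * scaled["C"])
        a = rank_within_type(rec)[["cne_id", "rank_within_type"]]
        b = rank_within_type(scaled)[["cne_id", "rank_within_type"]]
        pd.testing.assert_frame_equal(a, b)


class TestInfluenceTable:
    def test_bundle_network_scores(self, bundle):
        from cnegrn.grn import infer_downstream
        focal = bundle.focal_samples()
        trips = list(zip(bundle.truth_triplets.ttf, bundle.truth_triplets.cne,
                         bundle.truth_triplets.target))
        down = infer_downstream(
            bundle.expression.loc[bundle.ttf_ids, focal],
            bundle.openness[focal],
            bundle.expression.loc[
                sorted(set(bundle.truth_triplets.target)), focal], trips)
        b_pairs = {(c, t): 3.0 for t, c, _ in trips}
        b = pd.DataFrame([(r, t, v, 1) for (r, t), v in b_pairs.items()],
                         columns=["region_id", "tf", "B", "n_hits"])
        cons = {c.id: (c.cne_type, c.conservation) for c in bundle.cnes}
        table = influence_table(down, bundle.openness, b,
                                bundle.expression, bundle.expression,
                                bundle.samples_by_stage(), cons)
        assert len(table) == int(down["retained"].sum())
        r_cols = [c for c in table.columns if c.startswith("R_")]
        assert np.allclose(table["R"], table[r_cols].max(axis=1))
        assert np.allclose(table["W"], np.sqrt(table["R"] * table["C"]))
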