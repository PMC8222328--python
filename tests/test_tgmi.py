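"""Triplet scoring, permutation significance and TGMI ranking behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathreg.information import (
    conditional_mutual_information,
    discretize_equal_frequency,
)
from pathreg.io import ExpressionMatrix
from pathreg.tgmi import (
    TGMI,
    TGMIParams,
    build_network,
    permutation_pvalue,
    rank_regulators,
    run_tgmi,
    score_triplet,
    significant_mask,
    triplet_pvalues,
)


def make_matrix(prefix, values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix}{i+1}" for i in range(values.shape[0])],
        [f"s{j+1}" for j in range(values.shape[1])],
        values,
    )


class TestScoreTriplet:
    def test_exact_independence_all_zero(self):
        # full 2x2x2 factorial repeated: exactly independent discrete design
        t = np.tile([0, 0, 0, 0, 1, 1, 1, 1], 2)
        gi = np.tile([0, 0, 1, 1, 0, 0, 1, 1], 2)
        gj = np.tile([0, 1, 0, 1, 0, 1, 0, 1], 2)
        out = score_triplet(t, gi, gj, TGMIParams(n_bins=2))
        assert out == (0.0, 0.0, 0.0, 0.0)

    def test_identical_vectors_conditioning_identity(self):
        x = np.array([0.0, 1.0] * 8)
        out = score_triplet(x, x, x, TGMIParams(n_bins=2))
        assert out == (0.0, 0.0, 0.0, 0.0)

    def test_planted_chain_matches_info_theory_oracle(self, rng):
        n = 200
        t = rng.standard_normal(n)
        gi = t + 0.5 * rng.standard_normal(n)
        gj = t + 0.5 * rng.standard_normal(n)
        params = TGMIParams(n_bins=3)
        cmi_t_i, cmi_t_j, cmi_ij, mim = score_triplet(t, gi, gj, params)
        bt, bi, bj = (discretize_equal_frequency(v, 3) for v in (t, gi, gj))
        assert cmi_t_i == pytest.approx(
            conditional_mutual_information(bt, bi, bj), abs=1e-12
        )
        # well above the ~ (B-1)^2 B / (2n) = 0.06 plug-in bias scale
        noise_floor = 2 * (3 - 1) ** 2 * 3 / (2 * n)
        assert cmi_t_i > noise_floor and cmi_t_j > noise_floor
        assert mim == pytest.approx((cmi_t_i + cmi_t_j + cmi_ij) / 3, abs=1e-15)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            score_triplet([1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestPermutationPvalue:
    @staticmethod
    def mi_stat(a, b, c):
        ba = discretize_equal_frequency(a, 2)
        bb = discretize_equal_frequency(b, 2)
        from pathreg.information import mutual_information

        return mutual_information(ba, bb)

    def test_minimum_attainable_p(self, rng):
        a = np.arange(40.0)
        b = a + 0.01 * rng.standard_normal(40)
        p = permutation_pvalue(self.mi_stat, a, b, b, 99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_constant_first_argument_p_one(self, rng):
        a = np.ones(30)
        b = rng.standard_normal(30)
        p = permutation_pvalue(self.mi_stat, a, b, b, 49, seed=0)
        assert p == 1.0

    def test_deterministic_given_seed(self, rng):
        a, b = rng.standard_normal((2, 50))
        p1 = permutation_pvalue(self.mi_stat, a, b, b, 49, seed=5)
        p2 = permutation_pvalue(self.mi_stat, a, b, b, 49, seed=5)
        assert p1 == p2

    def test_r_floor_enforced(self, rng):
        a, b = rng.standard_normal((2, 20))
        with pytest.raises(ValueError):
            permutation_pvalue(self.mi_stat, a, b, b, 10, seed=0)

    def test_null_pvalues_uniform(self, rng):
        """Per-CMI permutation p-values on independent data follow the
        attainable uniform grid (KS test).

        Ties on the discrete statistic lattice are counted as exceedances, so
        the p-values can only be conservative: the one-sided KS test checks
        that the empirical CDF never sits significantly above the uniform
        (no anti-conservatism), and the rejection rate at the working level
        must match its nominal value.
        """
        own_rng = np.random.default_rng(555)
        params = TGMIParams(n_permutations=199, n_bins=3)
        pvals = []
        for _ in range(500):
            t, gi, gj = own_rng.standard_normal((3, 100))
            _, p = triplet_pvalues(
                t, gi, gj, params, seed=int(own_rng.integers(2**31))
            )
            pvals.append(p[0])
        assert stats.kstest(pvals, "uniform", alternative="greater").pvalue > 0.01
        assert 0.03 <= np.mean(np.asarray(pvals) <= 0.05) <= 0.07

    def test_null_pvalues_valid_at_coarse_bins(self, rng):
        """With the coarse 2-bin lattice, tie-inclusive counting may only make
        p-values conservative, never anti-conservative."""
        params = TGMIParams(n_permutations=99, n_bins=2)
        pvals = np.array([
            triplet_pvalues(
                *rng.standard_normal((3, 80)), params,
                seed=int(rng.integers(2**31)),
            )[1][0]
            for _ in range(300)
        ])
        for level in (0.01, 0.05, 0.1, 0.25):
            # binomial 3-sigma allowance above the nominal level
            slack = 3 * np.sqrt(level * (1 - level) / pvals.size)
            assert (pvals <= level).mean() <= level + slack


class TestRunTgmi:
    @pytest.fixture()
    def planted(self, rng):
        n = 200
        t_star = rng.standard_normal(n)
        tf_m = make_matrix("t", np.vstack([t_star, rng.standard_normal((2, n))]))
        g1 = t_star + 0.3 * rng.standard_normal(n)
        g2 = t_star + 0.3 * rng.standard_normal(n)
        path_m = make_matrix("g", np.vstack([g1, g2, rng.standard_normal((2, n))]))
        return tf_m, path_m

    def test_combinatorial_triplet_count(self, planted):
        tf_m, path_m, = planted
        triplets, _, _ = run_tgmi(tf_m, path_m, TGMIParams(n_permutations=49, seed=1))
        assert len(triplets) == 3 * 6

    def test_planted_regulator_recovered(self, planted):
        tf_m, path_m = planted
        triplets, network, ranking = run_tgmi(
            tf_m, path_m, TGMIParams(n_permutations=99, seed=1)
        )
        assert "t1" in set(ranking["tf_id"])
        row = ranking.loc[ranking["tf_id"] == "t1"].iloc[0]
        assert row["connectivity"] >= 2
        assert {"g1", "g2"} <= set(
            network.edges.loc[network.edges["tf_id"] == "t1", "gene_id"]
        )

    def test_determinism_bitwise(self, planted):
        tf_m, path_m = planted
        params = TGMIParams(n_permutations=49, seed=9)
        t1, _, r1 = run_tgmi(tf_m, path_m, params)
        t2, _, r2 = run_tgmi(tf_m, path_m, params)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_evaluation_order_invariance(self, planted):
        """P-values derive from (seed, tf, gene_i, gene_j), so shuffling the
        row order of the inputs never changes any triplet's statistics."""
        tf_m, path_m = planted
        params = TGMIParams(n_permutations=49, seed=9)
        t1, _, _ = run_tgmi(tf_m, path_m, params)
        tf_shuffled = tf_m.subset(list(reversed(tf_m.gene_ids)))
        path_shuffled = path_m.subset(list(reversed(path_m.gene_ids)))
        t2, _, _ = run_tgmi(tf_shuffled, path_shuffled, params)
        key = ["tf_id", "gene_i", "gene_j"]
        merged = t1.merge(t2, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(t1)
        for col in ("cmi_t_i", "p_t_i", "p_t_j", "p_ij", "mim"):
            np.testing.assert_array_equal(
                merged[f"{col}_a"].to_numpy(), merged[f"{col}_b"].to_numpy()
            )

    def test_pure_noise_yields_empty_or_tiny_ranking(self, rng):
        tf_m = make_matrix("t", rng.standard_normal((3, 80)))
        path_m = make_matrix("g", rng.standard_normal((4, 80)))
        triplets, network, ranking = run_tgmi(
            tf_m, path_m, TGMIParams(n_permutations=99, seed=3)
        )
        assert int(triplets["significant"].sum()) <= 2
        assert network.n_edges <= 4

    def test_alpha_monotonicity(self, planted):
        tf_m, path_m = planted
        results = TGMI(tf_m, path_m).fit(TGMIParams(n_permutations=99, seed=2, alpha=0.2))
        loose = {
            (t, g) for t, g in zip(results.network.edges["tf_id"],
                                   results.network.edges["gene_id"])
        }
        tight = results.at_alpha(0.01)
        tight_edges = {
            (t, g) for t, g in zip(tight.network.edges["tf_id"],
                                   tight.network.edges["gene_id"])
        }
        assert tight_edges <= loose

    def test_bh_option_never_adds_rejections(self, planted):
        tf_m, path_m = planted
        res = TGMI(tf_m, path_m).fit(TGMIParams(n_permutations=99, seed=2))
        raw = significant_mask(res.triplets, 0.05, "both-tf", bh=False)
        adj = significant_mask(res.triplets, 0.05, "both-tf", bh=True)
        assert adj.sum() <= raw.sum()

    def test_summary_mentions_counts(self, planted):
        tf_m, path_m = planted
        res = TGMI(tf_m, path_m).fit(TGMIParams(n_permutations=49, seed=1))
        text = res.summary()
        assert "triplets scored: 18" in text


class TestRankRegulators:
    @staticmethod
    def triplet_row(tf, gi, gj, mim=0.5, significant=True):
        return {
            "tf_id": tf, "gene_i": gi, "gene_j": gj,
            "cmi_t_i": mim, "cmi_t_j": mim, "cmi_ij": mim, "mim": mim,
            "p_t_i": 0.01, "p_t_j": 0.01, "p_ij": 0.01, "significant": significant,
        }

    def test_connectivity_ordering(self):
        rows = [
            self.triplet_row("A", "g1", "g2"),
            self.triplet_row("A", "g1", "g3"),
            self.triplet_row("B", "g1", "g2"),
        ]
        ranking = rank_regulators(pd.DataFrame(rows), top_k=10)
        assert ranking["tf_id"].tolist() == ["A", "B"]
        assert ranking["connectivity"].tolist() == [3, 2]
        assert ranking["rank"].tolist() == [1, 2]

    def test_triplet_count_tiebreak(self):
        rows = (
            [self.triplet_row("A", "g1", "g2")] * 5
            + [self.triplet_row("B", "g1", "g2")] * 3
        )
        ranking = rank_regulators(pd.DataFrame(rows), top_k=10)
        assert ranking["tf_id"].tolist() == ["A", "B"]

    def test_lexicographic_final_tiebreak(self):
        rows = [self.triplet_row(tf, "g1", "g2") for tf in ("Z", "A", "M")]
        ranking = rank_regulators(pd.DataFrame(rows), top_k=10)
        assert ranking["tf_id"].tolist() == ["A", "M", "Z"]

    def test_no_significant_triplets_empty_ranking(self):
        rows = [self.triplet_row("A", "g1", "g2", significant=False)]
        ranking = rank_regulators(pd.DataFrame(rows), top_k=10)
        assert ranking.empty

    def test_network_edge_weight_is_mean_mim(self):
        rows = [
            self.triplet_row("A", "g1", "g2", mim=0.4),
            self.triplet_row("A", "g1", "g3", mim=0.8),
        ]
        network = build_network(pd.DataFrame(rows))
        edge = network.edges.set_index(["tf_id", "gene_id"])
        assert edge.loc[("A", "g1"), "weight"] == pytest.approx(0.6)
        assert edge.loc[("A", "g1"), "support"] == 2
        assert edge.loc[("A", "g2"), "weight"] == pytest.approx(0.4)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"alpha": 1.0},
            {"n_permutations": 10},
            {"top_k": 0},
            {"significance_rule": "bogus"},
            {"n_bins": 1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TGMIParams(**kwargs)
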