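import itertools
import math

import numpy as np
import pytest
from scipy import stats

from epimm import (
    ExpressionMatrix,
    GeneSet,
    SchemaError,
    module_score,
    rank_de_test,
    region_score_correlation,
    ssgsea_score,
)
from epimm.signatures import SignatureScores, adjust_pvalues


class TestModuleScore:
    def test_constant_matrix_scores_zero(self, matrix_factory):
        m = matrix_factory(np.full((30, 4), 2.5))
        s = module_score(m, GeneSet("sig", ("g0", "g1")), n_bins=5, seed=0)
        np.testing.assert_allclose(s.scores, 0.0, atol=1e-12)

    def test_shift_invariance(self, matrix_factory):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(40, 6))
        sig = GeneSet("sig", ("g3", "g7", "g11"))
        a = module_score(matrix_factory(vals), sig, n_bins=8, seed=4)
        b = module_score(matrix_factory(vals + 11.0), sig, n_bins=8, seed=4)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-10)

    def test_matches_independent_step_by_step_oracle(self, matrix_factory):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(10, 5))
        m = matrix_factory(vals)
        sig = GeneSet("sig", ("g2", "g6"))
        n_bins, n_ctrl, seed = 3, 7, 11
        got = module_score(m, sig, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)

        # oracle: re-derive bins and control draws from the documented recipe
        avg = vals.mean(axis=1)
        order = sorted(range(10), key=lambda i: (avg[i], i))
        bin_of = {}
        for pos, gi in enumerate(order):
            bin_of[gi] = min((pos * n_bins) // 10, n_bins - 1)
        members = {
            b: np.array([g for g in range(10) if bin_of[g] == b]) for b in range(n_bins)
        }
        oracle_rng = np.random.default_rng(seed)
        ctrl = []
        for gname in sig.genes:
            gi = int(gname[1:])
            ctrl.append(oracle_rng.choice(members[bin_of[gi]], size=n_ctrl, replace=True))
        ctrl = np.concatenate(ctrl)
        sig_idx = [2, 6]
        expected = vals[sig_idx].mean(axis=0) - vals[ctrl].mean(axis=0)
        np.testing.assert_allclose(got.scores, expected, atol=1e-12)

    def test_reproducible_under_fixed_seed(self, matrix_factory):
        rng = np.random.default_rng(1)
        m = matrix_factory(rng.normal(size=(30, 4)))
        sig = GeneSet("sig", ("g0", "g5"))
        a = module_score(m, sig, n_bins=6, seed=3)
        b = module_score(m, sig, n_bins=6, seed=3)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_all_signature_genes_missing_is_error(self, matrix_factory):
        m = matrix_factory(np.zeros((30, 2)))
        with pytest.raises(SchemaError, match="ABSENT"):
            module_score(m, GeneSet("sig", ("ABSENT",)), n_bins=5)

    def test_params_recorded(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(0).normal(size=(30, 3)))
        s = module_score(m, GeneSet("sig", ("g1", "NOPE")), n_bins=5, n_ctrl=9, seed=2)
        assert s.params["n_bins"] == 5
        assert s.params["n_ctrl"] == 9
        assert s.params["missing_genes"] == ["NOPE"]


class TestSsgseaScore:
    def test_hand_enumerated_top_gene_alpha_zero(self, matrix_factory):
        # 5 distinct values; the set holds the top-ranked gene; alpha = 0.
        # Walking down the list: in-set cumfrac is 1 from step 1 on, out-of-set
        # cumfrac rises 0, 1/4, 2/4, 3/4, 1 -> sum of gaps = 2.5.
        m = matrix_factory(np.array([[5.0], [4.0], [3.0], [2.0], [1.0]]))
        s = ssgsea_score(m, GeneSet("top", ("g0",)), alpha=0.0)
        assert s.scores[0] == pytest.approx(2.5, rel=1e-12)

    def test_monotone_transform_invariance(self, matrix_factory):
        rng = np.random.default_rng(21)
        vals = rng.normal(size=(20, 3))
        sig = GeneSet("sig", ("g1", "g4", "g9"))
        a = ssgsea_score(matrix_factory(vals), sig, alpha=0.25)
        b = ssgsea_score(matrix_factory(np.exp(vals) + 3), sig, alpha=0.25)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-9)

    def test_identical_rankings_different_magnitudes_alpha_zero(self, matrix_factory):
        base = np.arange(8, dtype=float)
        m = matrix_factory(np.column_stack([base, base * 100 + 7]))
        s = ssgsea_score(m, GeneSet("sig", ("g2", "g5")), alpha=0.0)
        assert s.scores[0] == pytest.approx(s.scores[1], rel=1e-12)

    def test_signature_covering_all_genes_rejected(self, matrix_factory):
        m = matrix_factory(np.arange(6, dtype=float).reshape(3, 2))
        with pytest.raises(SchemaError, match="complement"):
            ssgsea_score(m, GeneSet("sig", ("g0", "g1", "g2")))

    def test_matches_running_sum_oracle_on_fixture(self, matrix_factory):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(10, 2))
        sig_genes = ("g0", "g3", "g8")
        got = ssgsea_score(matrix_factory(vals), GeneSet("sig", sig_genes), alpha=0.25)
        for u in range(2):
            x = vals[:, u]
            ranks = stats.rankdata(x)
            order = np.argsort(-x, kind="stable")
            in_set = np.array([f"g{i}" in sig_genes for i in order])
            w = np.where(in_set, ranks[order] ** 0.25, 0.0)
            score = 0.0
            cum_in = cum_out = 0.0
            for pos in range(10):
                cum_in += w[pos] / w.sum()
                cum_out += (0.0 if in_set[pos] else 1.0) / 7.0
                score += cum_in - cum_out
            assert got.scores[u] == pytest.approx(score, rel=1e-10)


class TestRankDETest:
    def make(self, a_vals, b_vals, matrix_factory):
        vals = np.array([list(a) + list(b) for a, b in zip(a_vals, b_vals)], float)
        units = [f"a{i}" for i in range(len(a_vals[0]))] + [
            f"b{i}" for i in range(len(b_vals[0]))
        ]
        genes = [f"g{i}" for i in range(len(a_vals))]
        m = ExpressionMatrix(genes, units, vals)
        ga = [u for u in units if u.startswith("a")]
        gb = [u for u in units if u.startswith("b")]
        return m, ga, gb

    def test_exact_wilcoxon_p_for_separated_triples(self, matrix_factory):
        m, ga, gb = self.make([[1, 2, 3]], [[4, 5, 6]], matrix_factory)
        tab = rank_de_test(m, ga, gb, min_lfc=0.0, min_pct=0.0)
        assert tab["p"].iloc[0] == pytest.approx(0.1, rel=1e-12)

    def test_identical_groups_prefiltered_out(self, matrix_factory):
        m, ga, gb = self.make([[1, 2, 3]], [[1, 2, 3]], matrix_factory)
        tab = rank_de_test(m, ga, gb, min_lfc=0.0, min_pct=0.0)
        assert len(tab) == 0

    def test_group_swap_negates_lfc_and_preserves_p(self, matrix_factory):
        rng = np.random.default_rng(6)
        a = rng.normal(1.0, 0.5, size=(5, 6))
        b = rng.normal(0.0, 0.5, size=(5, 6))
        m, ga, gb = self.make(a.tolist(), b.tolist(), matrix_factory)
        fwd = rank_de_test(m, ga, gb, min_lfc=0.0, min_pct=0.0).set_index("gene")
        rev = rank_de_test(m, gb, ga, min_lfc=0.0, min_pct=0.0).set_index("gene")
        for g in fwd.index:
            assert fwd.loc[g, "log_fc"] == pytest.approx(-rev.loc[g, "log_fc"], rel=1e-12)
            assert fwd.loc[g, "p"] == pytest.approx(rev.loc[g, "p"], rel=1e-12)

    def test_default_thresholds_keep_exactly_passing_genes(self, matrix_factory):
        # 5 genes: 2 pass both filters, 1 fails lfc, 1 fails pct, 1 fails both
        a = [
            [2.0, 2.1, 1.9],   # pass: lfc 2.0, pct 1.0
            [1.0, 1.2, 0.8],   # pass: lfc 1.0, pct 1.0
            [0.1, 0.2, 0.15],  # fail lfc (0.15)
            [0.4, 0.0, 0.0],   # lfc ~0.13 and pct 1/3 > 0.25 -> fails lfc
            [0.0, 0.0, 0.0],   # fail both
        ]
        b = [
            [0.0, 0.0, 0.0],
            [0.0, 0.1, 0.1],
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
        ]
        m, ga, gb = self.make(a, b, matrix_factory)
        tab = rank_de_test(m, ga, gb, min_lfc=0.25, min_pct=0.25)
        assert set(tab["gene"]) == {"g0", "g1"}
        assert (tab["p_adj"] >= tab["p"] - 1e-15).all()

    def test_bonferroni_and_bh_monotone(self):
        p = np.array([0.001, 0.02, 0.04, 0.5])
        bonf = adjust_pvalues(p, "bonferroni")
        bh = adjust_pvalues(p, "bh")
        np.testing.assert_allclose(bonf, np.minimum(p * 4, 1.0))
        assert (bh >= p - 1e-15).all() and (bh <= bonf + 1e-15).all()

    def test_empty_group_rejected(self, matrix_factory):
        m, ga, gb = self.make([[1, 2, 3]], [[4, 5, 6]], matrix_factory)
        with pytest.raises(ValueError):
            rank_de_test(m, [], gb)


def scores(name, units, values):
    return SignatureScores(name, list(units), np.asarray(values, float),
                           "module_score", {})


class TestRegionScoreCorrelation:
    def test_perfectly_monotone_gives_rho_one(self):
        a = scores("a", ["r1", "r2", "r3", "r4"], [0.1, 0.4, 0.9, 1.4])
        b = scores("b", ["r1", "r2", "r3", "r4"], [1, 2, 8, 9])
        rho, _ = region_score_correlation(a, b)
        assert rho == pytest.approx(1.0)

    def test_reversed_sequence_gives_rho_minus_one(self):
        a = scores("a", ["r1", "r2", "r3", "r4"], [1, 2, 3, 4])
        b = scores("b", ["r1", "r2", "r3", "r4"], [4, 3, 2, 1])
        rho, _ = region_score_correlation(a, b)
        assert rho == pytest.approx(-1.0)

    def test_small_n_p_matches_exhaustive_enumeration(self):
        x = [0.3, 1.2, 0.7, 2.2, 1.8]
        y = [0.2, 1.5, 0.4, 1.9, 2.5]
        a = scores("a", [f"r{i}" for i in range(5)], x)
        b = scores("b", [f"r{i}" for i in range(5)], y)
        rho, p = region_score_correlation(a, b)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = stats.pearsonr(rx, ry).statistic
        hits = sum(
            abs(stats.pearsonr(rx, ry[list(perm)]).statistic) >= abs(obs) - 1e-12
            for perm in itertools.permutations(range(5))
        )
        assert rho == pytest.approx(obs, rel=1e-12)
        assert p == pytest.approx(hits / math.factorial(5), rel=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=12)
        y = 0.8 * x + rng.normal(scale=0.5, size=12)
        a = scores("a", [f"r{i}" for i in range(12)], x)
        b = scores("b", [f"r{i}" for i in range(12)], y)
        rho, p = region_score_correlation(a, b)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, rel=1e-10)
        assert p == pytest.approx(ref_p, rel=1e-6)

    def test_explicit_pairing_maps_unit_ids(self):
        a = scores("a", ["p1", "p2", "p3"], [1, 2, 3])
        b = scores("b", ["q1", "q2", "q3"], [1, 2, 3])
        rho, _ = region_score_correlation(a, b, pairing={"p1": "q1", "p2": "q2", "p3": "q3"})
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        a = scores("a", ["r1", "r2"], [1, 2])
        b = scores("b", ["r1", "r2"], [1, 2])
        with pytest.raises(ValueError, match=">=3"):
            region_score_correlation(a, b)

    def test_constant_scores_give_zero(self):
        a = scores("a", ["r1", "r2", "r3"], [1, 1, 1])
        b = scores("b", ["r1", "r2", "r3"], [1, 2, 3])
        assert region_score_correlation(a, b) == (0.0, 1.0)
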