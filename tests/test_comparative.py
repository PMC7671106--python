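"""PCA, broken stick, BM ancestral states, phylogenetic MANOVA, Mk1 ASR, LDA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from ecomorph import trees
from ecomorph.comparative import (
    ComparativeError,
    _mk_loglik,
    _mk_transition,
    asr_transition_summary,
    bm_ancestral_states,
    broken_stick_retention,
    lda_classify,
    mk1_asr,
    pca,
    phylo_manova,
    phylomorphospace,
    wilks_lambda,
)


def _ztable(x, prefix="s"):
    x = np.asarray(x, float)
    return pd.DataFrame(
        x,
        index=[f"{prefix}{i}" for i in range(x.shape[0])],
        columns=[f"c{j}" for j in range(x.shape[1])],
    )


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_one_axis(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        res = pca(_ztable(x))
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one_and_scores_centered(self):
        rng = np.random.default_rng(3)
        res = pca(_ztable(rng.normal(size=(30, 5))))
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-12

    def test_loadings_orthonormal_and_reconstruction_exact(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 6))
        z = _ztable(x)
        res = pca(z)
        v = res.loadings.to_numpy()
        assert np.allclose(v.T @ v, np.eye(6), atol=1e-10)
        xc = x - x.mean(axis=0)
        rec = res.scores.to_numpy() @ v.T
        assert np.abs(rec - xc).max() < 1e-8

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        res = pca(_ztable(rng.normal(size=(25, 4))))
        for ax in res.loadings.columns:
            col = res.loadings[ax].to_numpy()
            assert col[np.abs(col).argmax()] > 0

    def test_isotropic_sample_splits_variance_evenly(self):
        rng = np.random.default_rng(6)
        res = pca(_ztable(rng.standard_normal((500, 2))))
        assert 0.45 < res.variance_fraction[0] < 0.55
        assert 0.45 < res.variance_fraction[1] < 0.55

    def test_rank_zero_rejected(self):
        with pytest.raises(ComparativeError, match="rank-0"):
            pca(_ztable(np.ones((5, 3))))


class TestBrokenStick:
    def test_expectations_sum_to_one(self):
        for p in (2, 5, 9):
            b = [sum(1.0 / i for i in range(j, p + 1)) / p for j in range(1, p + 1)]
            assert sum(b) == pytest.approx(1.0)

    def test_dominant_first_axis_retained(self):
        # p=2: b = (0.75, 0.25); 0.9 > 0.75 so axis 1 retained, 0.1 < 0.25 stops
        assert broken_stick_retention([0.9, 0.1]) == [0]

    def test_equal_fractions_retain_nothing(self):
        for p in (2, 4, 7):
            assert broken_stick_retention([1.0 / p] * p) == []

    def test_first_axis_failure_stops_immediately(self):
        # b = (0.6111, 0.2778, 0.1111); 0.5 < 0.6111 so nothing is retained
        assert broken_stick_retention([0.5, 0.3, 0.2]) == []

    def test_retention_is_a_prefix(self):
        assert broken_stick_retention([0.55, 0.25, 0.12, 0.05, 0.03]) == [0]


class TestBMAncestralStates:
    def test_star_tree_root_is_tip_mean(self):
        t = trees.parse_tree("(a:1,b:1,c:1,d:1);")
        vals = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 6.0}
        anc = bm_ancestral_states(t, vals)
        root = t.seed_node
        assert anc[root] == pytest.approx(3.0)

    def test_two_tip_closed_form(self):
        t = trees.parse_tree("(a:2,b:3);")
        anc = bm_ancestral_states(t, {"a": 10.0, "b": 0.0})
        expected = (10.0 / 2 + 0.0 / 3) / (1 / 2 + 1 / 3)
        assert anc[t.seed_node] == pytest.approx(expected)

    def test_constant_tips_give_constant_nodes(self):
        t = trees.parse_tree("((a:1,b:2):1,(c:3,(d:1,e:1):2):1);")
        anc = bm_ancestral_states(t, {k: 7.5 for k in "abcde"})
        assert all(v == pytest.approx(7.5) for v in anc.values())

    def test_missing_tip_value_rejected(self):
        t = trees.parse_tree("(a:1,b:1);")
        with pytest.raises(ComparativeError, match="missing"):
            bm_ancestral_states(t, {"a": 1.0})

    @pytest.mark.parametrize("newick", [
        "((a:1,b:2):1.5,c:3);",
        "((a:1,b:1):1,(c:2,d:0.5):2);",
        "(((a:1,b:2):1,c:1):2,(d:1,e:3):1);",
        "((a:0.3,(b:1,c:1):0.7):1,(d:2,(e:1,f:1):1):0.5);",
    ])
    def test_matches_gls_oracle_on_small_trees(self, newick):
        """Joint smoothing solution equals the closed-form GLS conditional mean."""
        t = trees.parse_tree(newick)
        labels = trees.tip_labels(t)
        rng = np.random.default_rng(hash(newick) % 2**31)
        vals = {lab: float(rng.normal()) for lab in labels}
        anc = bm_ancestral_states(t, vals)

        c, order = trees.vcv_matrix(t)
        y = np.array([vals[l] for l in order])
        cinv = np.linalg.inv(c)
        one = np.ones(len(order))
        mu = (one @ cinv @ y) / (one @ cinv @ one)
        depth = {}
        for node in t.preorder_node_iter():
            depth[node] = 0.0 if node.parent_node is None else (
                depth[node.parent_node] + node.edge.length)
        leaves = {l.taxon.label: l for l in t.leaf_node_iter()}
        for node in t.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            ancestors = set(node.ancestor_iter(inclusive=True))
            cov = np.array([
                depth[next(a for a in leaves[l].ancestor_iter(inclusive=True)
                           if a in ancestors)]
                for l in order
            ])
            oracle = mu + cov @ cinv @ (y - mu)
            assert anc[node] == pytest.approx(oracle, abs=1e-10)


class TestPhylomorphospace:
    def test_edges_connect_parent_child_and_nodes_covered(self):
        t = trees.parse_tree("((a:1,b:1):1,(c:1,d:1):1);")
        scores = pd.DataFrame(
            {"PC1": [0.0, 1.0, 2.0, 3.0], "PC2": [1.0, 0.0, 1.0, 0.0]},
            index=list("abcd"),
        )
        pms = phylomorphospace(t, scores)
        assert len(pms["edges"]) == 6  # 4 tips + 2 internal children
        assert len(pms["nodes"]) == 7
        for parent, child in pms["edges"]:
            assert parent in pms["nodes"] and child in pms["nodes"]


class TestWilks:
    def test_toy_matrix_matches_total_scatter_oracle(self):
        x = np.array([
            [1.0, 2.0], [1.5, 1.0], [2.0, 2.5],
            [5.0, 6.0], [5.5, 5.0], [6.0, 6.5],
        ])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        lam = wilks_lambda(x, g)
        # independent route: lambda = det(W) / det(T), T = total scatter
        xc = x - x.mean(axis=0)
        t = xc.T @ xc
        w = np.zeros((2, 2))
        for lev in ("a", "b"):
            d = x[g == lev] - x[g == lev].mean(axis=0)
            w += d.T @ d
        assert lam == pytest.approx(np.linalg.det(w) / np.linalg.det(t), abs=1e-10)

    def test_more_characters_than_residual_df_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 5))
        g = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(ComparativeError, match="singular"):
            wilks_lambda(x, g)


class TestPhyloManova:
    def _setup(self, n=16, p=3, shift=0.0, seed=0):
        from tests.conftest import star_newick

        t = trees.parse_tree(star_newick(n))
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, p))
        g = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        x[g == "b"] += shift
        labels = [f"sp{i:02d}" for i in range(1, n + 1)]
        zt = pd.DataFrame(x, index=labels, columns=[f"c{j}" for j in range(p)])
        return t, zt, pd.Series(g, index=labels)

    def test_maximal_separation_gives_minimal_p(self):
        t, zt, g = self._setup(shift=10.0)
        res = phylo_manova(t, zt, g, nsim=99, seed=1)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_p_value_reproducible_under_seed(self):
        t, zt, g = self._setup(shift=0.5)
        r1 = phylo_manova(t, zt, g, nsim=199, seed=11)
        r2 = phylo_manova(t, zt, g, nsim=199, seed=11)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.wilks_simulated, r2.wilks_simulated)

    def test_p_value_bounds(self):
        t, zt, g = self._setup(shift=0.0, seed=5)
        res = phylo_manova(t, zt, g, nsim=99, seed=2)
        assert 1.0 / 100.0 <= res.p_value <= 1.0

    def test_nsim_floor_enforced(self):
        t, zt, g = self._setup()
        with pytest.raises(ComparativeError, match="nsim"):
            phylo_manova(t, zt, g, nsim=10, seed=0)


class TestMk1:
    def test_transition_matrix_matches_matrix_exponential(self):
        for k in (2, 3, 6):
            q = 0.37
            rate = np.full((k, k), q)
            np.fill_diagonal(rate, -(k - 1) * q)
            for t in (0.1, 1.0, 5.0):
                assert np.allclose(
                    _mk_transition(k, q, t), expm(rate * t), atol=1e-12
                )

    def test_uniform_tip_states_reconstruct_uniformly(self):
        t = trees.parse_tree("((a:1,b:1):1,(c:1,d:1):1);")
        asr = mk1_asr(t, {k: "A" for k in "abcd"}, states=("A", "B"),
                      rate=0.01)
        for probs in asr.node_marginals.values():
            assert probs[asr.states.index("A")] >= 0.99

    def test_likelihood_matches_enumeration_oracle_on_four_tips(self):
        newick = "((a:0.8,b:1.2):0.5,(c:1.0,d:0.7):0.9);"
        t = trees.parse_tree(newick)
        states = ("A", "B")
        tip_states = {"a": "A", "b": "A", "c": "B", "d": "A"}
        q = 0.31
        ll, _ = _mk_loglik(t, tip_states, states, q)

        # brute force: sum over all internal-node state assignments,
        # transition probabilities from the matrix exponential
        k = 2
        rate = np.full((k, k), q)
        np.fill_diagonal(rate, -(k - 1) * q)
        pm = {bl: expm(rate * bl) for bl in (0.8, 1.2, 0.5, 1.0, 0.7, 0.9)}
        sidx = {"A": 0, "B": 1}
        total = 0.0
        for root, left, right in itertools.product(range(k), repeat=3):
            term = 1.0 / k
            term *= pm[0.5][root, left] * pm[0.9][root, right]
            term *= (pm[0.8][left, sidx[tip_states["a"]]]
                     * pm[1.2][left, sidx[tip_states["b"]]])
            term *= (pm[1.0][right, sidx[tip_states["c"]]]
                     * pm[0.7][right, sidx[tip_states["d"]]])
            total += term
        assert ll == pytest.approx(np.log(total), abs=1e-8)

    def test_two_tip_marginals_match_hand_computation(self):
        q, tlen = 0.2, 1.5
        t = trees.parse_tree(f"(a:{tlen},b:{tlen});")
        asr = mk1_asr(t, {"a": "A", "b": "B"}, states=("A", "B"), rate=q)
        p = _mk_transition(2, q, tlen)
        # root marginal: pi_s * P(s->A) * P(s->B), normalized
        w = np.array([0.5 * p[0, 0] * p[0, 1], 0.5 * p[1, 0] * p[1, 1]])
        expected = w / w.sum()
        root_id = "node_0"
        assert asr.node_marginals[root_id] == pytest.approx(expected, abs=1e-12)
        # by symmetry the root is equivocal
        assert expected[0] == pytest.approx(0.5)

    def test_log_likelihood_invariant_to_rerooting(self):
        q = 0.4
        tip_states = {"a": "A", "b": "B", "c": "A", "d": "B"}
        # same unrooted tree, two rootings
        t1 = trees.parse_tree("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = trees.parse_tree("(a:1,b:1,(c:1,d:1):2);")
        ll1, _ = _mk_loglik(t1, tip_states, ("A", "B"), q)
        ll2, _ = _mk_loglik(t2, tip_states, ("A", "B"), q)
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_rate_estimate_positive_and_marginals_normalized(self):
        t = trees.parse_tree("((a:1,b:1):1,((c:1,d:1):1,e:2):1);")
        asr = mk1_asr(t, {"a": "A", "b": "A", "c": "B", "d": "B", "e": "A"})
        assert asr.rate > 0
        for probs in asr.node_marginals.values():
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_tip_marginals_are_point_masses(self):
        t = trees.parse_tree("(a:1,b:1);")
        asr = mk1_asr(t, {"a": "A", "b": "B"}, states=("A", "B"), rate=0.3)
        for nid, label in asr.node_labels.items():
            if label in ("a", "b"):
                assert asr.node_marginals[nid].max() == pytest.approx(1.0)

    def test_unknown_state_rejected(self):
        t = trees.parse_tree("(a:1,b:1);")
        with pytest.raises(ComparativeError, match="unknown state"):
            mk1_asr(t, {"a": "A", "b": "Z"}, states=("A", "B"))


class TestTransitionSummary:
    def test_uniform_states_give_no_transitions(self):
        t = trees.parse_tree("((a:1,b:1):1,(c:1,d:1):1);")
        asr = mk1_asr(t, {k: "A" for k in "abcd"}, states=("A", "B"), rate=0.05)
        assert asr_transition_summary(asr) == []

    def test_single_derived_clade_yields_stem_edge(self):
        t = trees.parse_tree(
            "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
        )
        states = {k: "A" for k in "abefgh"} | {"c": "B", "d": "B"}
        asr = mk1_asr(t, states, states=("A", "B"), rate=0.05)
        shifts = asr_transition_summary(asr)
        assert len(shifts) == 1
        assert shifts[0]["from_state"] == "A" and shifts[0]["to_state"] == "B"

    def test_two_derived_clades_yield_two_edges(self):
        t = trees.parse_tree(
            "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
        )
        states = {k: "A" for k in "abef"} | {k: "B" for k in "cdgh"}
        asr = mk1_asr(t, states, states=("A", "B"), rate=0.05)
        assert len(asr_transition_summary(asr)) == 2


class TestLDA:
    def test_widely_separated_classes_classified_perfectly(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(20, 1, 30)])
        zt = _ztable(x[:, None])
        labels = pd.Series(["lo"] * 30 + ["hi"] * 30, index=zt.index)
        res = lda_classify(zt, labels)
        assert res.accuracy == 1.0
        assert res.mismatches == []

    def test_one_dimensional_closed_form_log_odds(self):
        """Equal-prior 1-D LDA: log-odds = (mu_a - mu_b)/s^2 * (x - midpoint),
        so the decision boundary sits at the midpoint of the class means."""
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])[:, None]
        zt = _ztable(x)
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=zt.index)
        res = lda_classify(zt, labels, priors="uniform")
        assert res.predicted.tolist() == ["a"] * 3 + ["b"] * 3
        mu_a, mu_b = 1.0, 11.0
        s2 = 4.0 / (6 - 2)  # pooled within-class variance
        log_odds = np.log(res.posterior["a"] / res.posterior["b"])
        expected = (mu_a - mu_b) / s2 * (x[:, 0] - (mu_a + mu_b) / 2)
        assert log_odds.to_numpy() == pytest.approx(expected, rel=1e-10)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(8)
        zt = _ztable(rng.normal(size=(40, 3)))
        labels = pd.Series(rng.choice(["a", "b", "c"], 40), index=zt.index)
        res = lda_classify(zt, labels)
        assert np.allclose(res.posterior.sum(axis=1), 1.0, atol=1e-12)

    def test_confusion_rows_sum_to_class_sizes(self):
        rng = np.random.default_rng(9)
        zt = _ztable(rng.normal(size=(50, 2)))
        labels = pd.Series(["a"] * 20 + ["b"] * 30, index=zt.index)
        res = lda_classify(zt, labels)
        assert res.confusion.sum(axis=1).tolist() == [20, 30]

    def test_matches_reference_implementation_on_gaussian_mixture(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(10)
        n, p = 120, 4
        centers = np.array([[0, 0, 0, 0], [3, 0, 0, 0], [0, 3, 0, 0]], float)
        y = rng.integers(0, 3, n)
        x = rng.standard_normal((n, p)) + centers[y]
        zt = _ztable(x)
        labels = pd.Series([f"c{v}" for v in y], index=zt.index)
        mine = lda_classify(zt, labels)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(x, labels.values)
        order = [list(ref.classes_).index(c) for c in mine.classes]
        assert (mine.predicted.values == ref.predict(x)).all()
        assert np.abs(
            mine.posterior.to_numpy() - ref.predict_proba(x)[:, order]
        ).max() < 1e-6
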