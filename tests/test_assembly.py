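import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from planktonet import (beta_mntd, beta_nti, classify_assembly, fit_ncm,
                        raup_crick_bray, ses_mntd, simulate_neutral_dataset,
                        simulate_tree)
from planktonet.assembly import cophenetic_matrix
from conftest import brute_force_beta_mntd


class TestFitNCM:
    def test_perfect_neutral_frequencies_give_r2_one(self):
        # build occupancy frequencies exactly on the Sloan curve, then embed
        # them in a table whose detection pattern matches
        from scipy.stats import beta as beta_dist
        rng = np.random.default_rng(2)
        n_samples, N, m = 200, 1000, 0.2
        p = np.sort(rng.dirichlet(np.ones(40)))[::-1]
        d = np.log(2) / N
        f = beta_dist.sf(d, N * m * p, N * m * (1 - p))
        counts = np.zeros((n_samples, 40), dtype=int)
        for j, (pj, fj) in enumerate(zip(p, f)):
            k = int(round(fj * n_samples))
            rows = rng.choice(n_samples, size=max(k, 1), replace=False)
            counts[rows, j] = max(int(round(pj * N * n_samples / max(k, 1))), 1)
        table = pd.DataFrame(counts + 0,
                             columns=[f"t{j}" for j in range(40)])
        table["pad"] = np.maximum(N - table.sum(axis=1), 1)
        fit = fit_ncm(table)
        assert fit.r2 > 0.93    # near-perfect by construction
        assert 0 < fit.m <= 1

    def test_recovers_migration_within_tolerance(self):
        ds = simulate_neutral_dataset(50, 200, 1000, 0.1, seed=17)
        fit = fit_ncm(ds.table)
        assert abs(fit.Nm - 100) / 100 < 0.25
        assert fit.r2 > 0.9
        assert fit.N == pytest.approx(1000)

    def test_prediction_bounds_bracket_predictions(self, neutral_dataset):
        fit = fit_ncm(neutral_dataset.table)
        assert (fit.freq["lower"] <= fit.freq["predicted"] + 1e-9).all()
        assert (fit.freq["upper"] >= fit.freq["predicted"] - 1e-9).all()
        assert fit.freq["predicted"].between(0, 1).all()


class TestSesMntd:
    def test_cherry_sample_mntd_is_tip_distance(self, toy_tree):
        t = pd.DataFrame([[1, 1, 0, 0, 0, 0]], index=["s"],
                         columns=list("abcdef"))
        out = ses_mntd(t, toy_tree, n_null=99, seed=0)
        assert out.loc["s", "mntd"] == pytest.approx(2.0)  # a-b distance

    def test_full_community_null_is_degenerate(self, toy_tree):
        t = pd.DataFrame([[1] * 6], index=["s"], columns=list("abcdef"))
        out = ses_mntd(t, toy_tree, n_null=99, seed=0)
        assert np.isnan(out.loc["s", "ses"])

    def test_null_generated_data_standardizes_to_unit_normal(self):
        tree = simulate_tree(60, seed=21)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(22)
        counts = np.zeros((150, 60), dtype=int)
        for i in range(150):
            idx = rng.choice(60, 15, replace=False)
            counts[i, idx] = rng.integers(1, 50, 15)
        t = pd.DataFrame(counts, index=[f"s{i}" for i in range(150)],
                         columns=tips)
        out = ses_mntd(t, tree, n_null=199, seed=23)
        assert abs(out["ses"].mean()) < 0.15
        assert 0.85 < out["ses"].std() < 1.15


class TestBetaMntd:
    def test_identical_communities_have_zero_turnover(self, toy_tree):
        t = pd.DataFrame([[3, 1, 0, 2, 0, 0]] * 2, index=["s1", "s2"],
                         columns=list("abcdef"))
        assert beta_mntd(t, toy_tree).loc["s1", "s2"] == pytest.approx(0.0)

    def test_single_taxon_pair_is_cophenetic_distance(self, toy_tree):
        t = pd.DataFrame([[1, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 1]],
                         index=["s1", "s2"], columns=list("abcdef"))
        # a and f: a->root = 1+1+1, f->root = 1+2
        assert beta_mntd(t, toy_tree).loc["s1", "s2"] == pytest.approx(6.0)

    @pytest.mark.parametrize("weighted", [True, False])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_double_loop(self, weighted, seed):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(3, 9))
        n_samples = int(rng.integers(2, 5))
        tree = simulate_tree(n_tips, seed=seed + 50)
        tips = [t.name for t in tree.tips()]
        counts = rng.integers(0, 6, size=(n_samples, n_tips))
        counts[:, 0] += 1                      # no empty community
        t = pd.DataFrame(counts, index=[f"s{i}" for i in range(n_samples)],
                         columns=tips)
        D = cophenetic_matrix(tree, tips)
        expected = brute_force_beta_mntd(counts.astype(float), D, weighted)
        got = beta_mntd(t, tree, weighted=weighted).to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-9)


class TestBetaNti:
    def test_matrix_is_symmetric_with_nan_diagonal(self, neutral_dataset):
        nti = beta_nti(neutral_dataset.table.iloc[:6], neutral_dataset.tree,
                       n_null=99, seed=1)
        m = nti.to_numpy()
        assert np.isnan(np.diag(m)).all()
        assert np.allclose(m, m.T, equal_nan=True)

    def test_seed_determinism(self, neutral_dataset):
        a = beta_nti(neutral_dataset.table.iloc[:4], neutral_dataset.tree,
                     n_null=99, seed=5)
        b = beta_nti(neutral_dataset.table.iloc[:4], neutral_dataset.tree,
                     n_null=99, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestRaupCrick:
    def test_identical_samples_hit_lower_boundary(self):
        t = pd.DataFrame([[40, 30, 20, 10, 5]] * 2, index=["s1", "s2"],
                         columns=[f"t{i}" for i in range(5)])
        rc = raup_crick_bray(t, n_null=99, seed=0)
        assert rc.loc["s1", "s2"] == pytest.approx(-1.0)

    def test_values_bounded_and_symmetric(self, neutral_dataset):
        rc = raup_crick_bray(neutral_dataset.table.iloc[:6], n_null=99,
                             seed=2)
        m = rc.to_numpy()
        off = m[~np.isnan(m)]
        assert (off >= -1).all() and (off <= 1).all()
        assert np.allclose(m, m.T, equal_nan=True)


class TestClassifyAssembly:
    def _square(self, vals, ids):
        m = pd.DataFrame(np.nan, index=ids, columns=ids)
        for (a, b), v in vals.items():
            m.loc[a, b] = m.loc[b, a] = v
        return m

    def test_threshold_rules(self):
        ids = list("abcd")
        bnti = self._square({("a", "b"): -2.5, ("a", "c"): 2.5,
                             ("a", "d"): 1.0, ("b", "c"): -1.0,
                             ("b", "d"): 0.0, ("c", "d"): 2.0}, ids)
        rc = self._square({("a", "b"): 0.0, ("a", "c"): 0.0,
                           ("a", "d"): 0.97, ("b", "c"): -0.97,
                           ("b", "d"): 0.5, ("c", "d"): 0.0}, ids)
        res = classify_assembly(bnti, rc)
        got = res.pairs.set_index(["sample_i", "sample_j"])["process"]
        assert got[("a", "b")] == "homogeneous selection"   # bNTI < -2
        assert got[("a", "c")] == "variable selection"      # bNTI > +2
        assert got[("a", "d")] == "dispersal limitation"    # RC > 0.95
        assert got[("b", "c")] == "homogenizing dispersal"  # RC < -0.95
        assert got[("b", "d")] == "drift"                   # |RC| <= 0.95
        assert got[("c", "d")] == "drift"                   # |bNTI| = 2 is stochastic
        assert sum(res.fractions.values()) == pytest.approx(1.0)

    def test_missing_rc_for_stochastic_pair_raises(self):
        ids = ["a", "b"]
        bnti = self._square({("a", "b"): 0.5}, ids)
        with pytest.raises(ValueError, match="RCbray required"):
            classify_assembly(bnti, None)

    def test_degenerate_pairs_excluded_with_count(self):
        ids = ["a", "b", "c"]
        bnti = self._square({("a", "b"): 3.0, ("b", "c"): -3.0}, ids)
        res = classify_assembly(bnti, None)
        assert res.excluded_pairs == 1
        assert len(res.pairs) == 2
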