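"""Tree handling and naive vs phylogenetically corrected logistic regression."""

import math

import numpy as np
import pytest
from scipy import stats

from traitscope.phylo import (
    LogisticFit,
    Phylogeny,
    lrt,
    naive_logistic,
    phylo_logistic,
    phylo_lrt,
    prune_to_overlap,
)
from traitscope.synthetic_data import gen_tree, sim_binary_trait_on_tree, sim_logistic_on_tree

NEWICK5 = "((A_a:1,B_b:1):1,(C_c:1,(D_d:0.5,E_e:0.5):0.5):1);"


def star_tree(n):
    return Phylogeny.from_newick(
        "(" + ",".join(f"s{i}:1" for i in range(n)) + ");", is_path=False
    )


class TestPrune:
    def test_full_overlap_drops_nothing(self):
        tree = Phylogeny.from_newick(NEWICK5, is_path=False)
        pruned, dropped = prune_to_overlap(tree, ["A a", "B b", "C c"])
        assert len(pruned) == 3 and dropped == []

    def test_missing_species_reported(self):
        tree = Phylogeny.from_newick(NEWICK5, is_path=False)
        pruned, dropped = prune_to_overlap(tree, ["A a", "Zz z"])
        assert dropped == ["Zz z"] and len(pruned) == 1

    def test_idempotent(self):
        tree = Phylogeny.from_newick(NEWICK5, is_path=False)
        once, _ = prune_to_overlap(tree, ["A a", "C c", "D d"])
        twice, dropped = prune_to_overlap(once, ["A a", "C c", "D d"])
        assert dropped == []
        assert sorted(twice.tip_names) == sorted(once.tip_names)
        assert twice.height == pytest.approx(once.height)

    def test_zero_overlap_rejected(self):
        tree = Phylogeny.from_newick(NEWICK5, is_path=False)
        with pytest.raises(ValueError, match="no overlap"):
            prune_to_overlap(tree, ["X x"])

    def test_name_normalization_case_and_underscores(self):
        tree = Phylogeny.from_newick(NEWICK5, is_path=False)
        pruned, dropped = prune_to_overlap(tree, ["a_A".lower(), "B B"])
        assert dropped == [] and len(pruned) == 2

    def test_suppressed_unifurcations_sum_lengths(self):
        tree = Phylogeny.from_newick("((A:1,B:1):2,C:3);", is_path=False)
        pruned, _ = prune_to_overlap(tree, ["A", "C"])
        # A keeps its root-to-tip path length: 1 + 2
        S, T = pruned.shared_depth_matrix(["A", "C"])
        assert T[0] == pytest.approx(3.0) and T[1] == pytest.approx(3.0)


def grid_loglik_oracle(y, x, betas_grid):
    """Direct Bernoulli log-likelihood evaluated on a parameter grid."""
    best = -np.inf
    for b0 in betas_grid:
        for b1 in betas_grid:
            eta = b0 + b1 * np.asarray(x)
            ll = np.sum(np.log(stats.logistic.cdf((2 * np.asarray(y) - 1) * eta)))
            best = max(best, ll)
    return best


class TestNaiveLogistic:
    def test_null_data_flat_fit(self):
        y = np.array([0, 1] * 30)
        x = np.array([0.0, 0.0, 1.0, 1.0] * 15)
        fit = naive_logistic(y, x)
        assert abs(fit.beta1) < 0.7
        assert fit.loglik == pytest.approx(len(y) * math.log(0.5), rel=0.05)

    def test_grouped_closed_form_log_odds_ratio(self):
        # 8/10 positive with x=1 vs 2/10 with x=0: beta1 = log(16)
        y = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        x = [1.0] * 10 + [0.0] * 10
        fit = naive_logistic(y, x)
        assert fit.beta1 == pytest.approx(math.log(16.0), abs=1e-5)
        # grid oracle never beats the MLE
        assert fit.loglik >= grid_loglik_oracle(y, x, np.linspace(-3, 3, 25)) - 1e-6

    def test_separation_flagged(self):
        y = [0] * 10 + [1] * 10
        x = [0.0] * 10 + [1.0] * 10
        fit = naive_logistic(y, x)
        assert "separation" in fit.flags

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            naive_logistic([1, 1, 1, 1], [0.0, 1.0, 0.0, 1.0])

    def test_missing_x_dropped_and_counted(self):
        y = [0, 1, 0, 1, 0, 1]
        x = [0.0, 1.0, None, 1.0, 0.0, None]
        fit = naive_logistic(y, x)
        assert fit.n == 4 and fit.n_dropped == 2

    def test_categorical_dummy_coding(self):
        y = [0, 1, 0, 1, 1, 0, 1, 0]
        x = ["coccus", "rod", "coccus", "rod", "rod", "coccus", "rod", "coccus"]
        fit = naive_logistic(y, x, reference_level="coccus")
        assert fit.predictor_names == ["intercept", "x[rod]"]


class TestPhyloLogistic:
    def test_star_tree_equals_naive(self, rng):
        for trial in range(4):
            n = 50
            tree = star_tree(n)
            x = rng.integers(0, 2, n).astype(float)
            y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 0.8 * x)))).astype(int)
            if len(np.unique(y)) < 2:
                continue
            naive = naive_logistic(y, x)
            phylo = phylo_logistic(y, x, tree, [f"s{i}" for i in range(n)], seed=trial)
            assert np.allclose(phylo.betas, naive.betas, atol=1e-4)
            assert phylo.loglik == pytest.approx(naive.loglik, abs=1e-6)
            assert phylo.sigma2 == 0.0

    def test_forced_zero_signal_equals_naive(self, rng):
        tree = gen_tree(40, seed=5)
        x = rng.integers(0, 2, 40).astype(float)
        y = sim_logistic_on_tree(tree, x, 0.0, 1.0, 0.8, 1.0, seed=6)
        naive = naive_logistic(y, x)
        forced = phylo_logistic(y, x, tree, seed=0, fix_sigma2=0.0)
        assert np.allclose(forced.betas, naive.betas, atol=1e-4)

    def test_corrected_loglik_never_below_naive(self, rng):
        tree = gen_tree(60, seed=9)
        x = rng.integers(0, 2, 60).astype(float)
        y = sim_logistic_on_tree(tree, x, -0.3, 0.5, 1.0, 0.5, seed=10)
        fit = phylo_logistic(y, x, tree, seed=1)
        naive = naive_logistic(y, x)
        assert fit.loglik >= naive.loglik - 1e-6

    def test_missing_tree_species_dropped(self, rng):
        tree = gen_tree(30, seed=2)
        names = tree.tip_names + ["Ghost species"]
        x = rng.integers(0, 2, 31).astype(float)
        y = np.concatenate([rng.integers(0, 2, 30), [1]])
        while len(np.unique(y[:30])) < 2:  # pragma: no cover
            y = np.concatenate([rng.integers(0, 2, 30), [1]])
        fit = phylo_logistic(y, x, tree, names, seed=0, n_starts=1)
        assert fit.n == 30 and fit.n_dropped == 1

    def test_clade_structured_null_corrects_naive_inflation(self):
        """Both traits evolve on the tree with no true association: the
        naive LRT rejects far above nominal, the corrected LRT stays near
        nominal, and the corrected p-value is usually the larger one."""
        wins = total = naive_rej = phylo_rej = 0
        for s in range(60):
            tree = gen_tree(100, seed=500 + s)
            y_map = sim_binary_trait_on_tree(tree, 0.4, 0.4, seed=600 + s)
            y = np.array([y_map[t] for t in tree.tip_names])
            x_map = sim_binary_trait_on_tree(tree, 0.4, 0.4, seed=9600 + s)
            x = np.array([x_map[t] for t in tree.tip_names], dtype=float)
            if y.sum() < 5 or y.sum() > 95 or len(set(x)) < 2:
                continue
            fit_n, null_n = naive_logistic(y, x), naive_logistic(y, None)
            _, p_n = lrt(fit_n, null_n)
            _, _, _, p_p = phylo_lrt(y, x, tree, seed=s, n_starts=1)
            total += 1
            wins += p_p >= p_n - 1e-12
            naive_rej += p_n <= 0.05
            phylo_rej += p_p <= 0.05
        assert total >= 40
        assert wins / total >= 0.65
        assert phylo_rej / total <= 0.12
        assert phylo_rej <= naive_rej / 2  # the inflation is substantially removed


class TestPhyloLRTNull:
    def test_null_rejection_rate_conservative(self):
        """Under the no-effect GLMM null the corrected LRT rejects <= nominal.

        The signal parameter sits on a boundary under the null, which makes
        the chi-square reference conservative; rejections at 0.05 should not
        exceed nominal by more than Monte-Carlo noise.
        """
        hits = total = 0
        for s in range(60):
            tree = gen_tree(80, seed=3000 + s)
            rng = np.random.default_rng(4000 + s)
            x = rng.integers(0, 2, 80).astype(float)
            y = sim_logistic_on_tree(tree, np.zeros(80), 0.0, 0.0, 1.0, 1.0, seed=5000 + s)
            if y.sum() < 5 or y.sum() > 75 or len(set(x)) < 2:
                continue
            _, _, _, p = phylo_lrt(y, x, tree, seed=s, n_starts=1)
            total += 1
            hits += p <= 0.05
        assert total >= 40
        assert hits / total <= 0.10


class TestLRT:
    def _fit(self, ll, n_betas=2, n=50):
        return LogisticFit(betas=np.zeros(n_betas), loglik=ll, converged=True, n=n, method="naive")

    def test_equal_logliks(self):
        stat, p = lrt(self._fit(-30.0), self._fit(-30.0, n_betas=1))
        assert stat == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        stat, p = lrt(self._fit(-30.0), self._fit(-30.0 - 3.841 / 2, n_betas=1))
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_df_two_zero_statistic(self):
        stat, p = lrt(self._fit(-30.0, n_betas=3), self._fit(-30.0, n_betas=1))
        assert stat == 0.0 and p == 1.0

    def test_optimization_failure_detected(self):
        with pytest.raises(ValueError, match="optimization failure"):
            lrt(self._fit(-31.0), self._fit(-30.0, n_betas=1))

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError, match="observation counts"):
            lrt(self._fit(-30.0, n=50), self._fit(-31.0, n_betas=1, n=40))
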