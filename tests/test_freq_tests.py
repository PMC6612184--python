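"""Binomial, chi-square and randomization-test behavior."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from traitscope.freq_tests import (
    benjamini_hochberg,
    binomial_proportion,
    chi_square_overall,
    pairwise_proportion_contrast,
    randomization_test,
)


class TestBinomial:
    @pytest.mark.parametrize(
        "k,n,p,se",
        [(0, 10, 0.0, 0.0), (5, 10, 0.5, 0.15811388), (10, 10, 1.0, 0.0)],
    )
    def test_closed_form(self, k, n, p, se):
        p_hat, se_hat = binomial_proportion(k, n)
        assert p_hat == pytest.approx(p)
        assert se_hat == pytest.approx(se, abs=1e-7)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_proportion(0, 0)


class TestChiSquare:
    def test_equal_proportions_give_zero(self):
        stat, df, p, _ = chi_square_overall([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        stat, df, p, _ = chi_square_overall([[20, 10], [10, 20]])
        assert stat == pytest.approx(6.6667, abs=1e-4)
        assert df == 1 and p == pytest.approx(0.00982, abs=1e-5)

    def test_complete_separation_table(self):
        stat, df, p, flags = chi_square_overall([[5, 0], [0, 5]])
        assert stat == pytest.approx(10.0) and df == 1
        assert "low_expected_cell" in flags

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_overall([[0, 0], [5, 5]])

    @given(
        st.lists(st.integers(1, 30), min_size=4, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_pearson_matches_brute_force_oracle(self, cells):
        # independent oracle: direct sum of (O-E)^2/E over all cells
        obs = np.array(cells, dtype=float).reshape(2, 2)
        total = obs.sum()
        expected = [
            [obs[i].sum() * obs[:, j].sum() / total for j in range(2)] for i in range(2)
        ]
        oracle = sum(
            (obs[i, j] - expected[i][j]) ** 2 / expected[i][j]
            for i in range(2)
            for j in range(2)
        )
        stat, _, _, _ = chi_square_overall(obs)
        assert stat == pytest.approx(oracle)


class TestPairwiseContrast:
    def test_equal_groups(self):
        res = pairwise_proportion_contrast(5, 10, 5, 10)
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)
        assert res.direction == "none"

    def test_closed_form_z(self):
        res = pairwise_proportion_contrast(9, 10, 1, 10)
        assert res.statistic == pytest.approx(0.8 / math.sqrt(2 * 0.009), abs=1e-3)

    def test_common_boundary_convention(self):
        res = pairwise_proportion_contrast(0, 10, 0, 20)
        assert res.p_value == 1.0 and "boundary" in res.flags

    @given(
        st.integers(1, 20), st.integers(1, 20), st.integers(1, 20), st.integers(1, 20)
    )
    @settings(max_examples=60, deadline=None)
    def test_pooled_z_squared_equals_chi_square(self, k1, d1, k2, d2):
        n1, n2 = k1 + d1, k2 + d2
        res = pairwise_proportion_contrast(k1, n1, k2, n2, pooled=True)
        stat, _, _, _ = chi_square_overall([[k1, k2], [d1, d2]])
        assert res.statistic**2 == pytest.approx(stat, rel=1e-9)


def _exact_oracle(labels, outcomes):
    """Brute-force exact permutation p-values over all label assignments."""
    outcomes = [o if isinstance(o, frozenset) else frozenset([o]) for o in outcomes]
    levels = sorted({l for o in outcomes for l in o})
    n = len(outcomes)
    n1 = sum(1 for l in labels if l == labels[0])

    def spread(assignment):
        a = [outcomes[i] for i in assignment]
        b = [outcomes[i] for i in range(n) if i not in set(assignment)]
        out = []
        for lvl in levels:
            pa = sum(lvl in o for o in a) / len(a)
            pb = sum(lvl in o for o in b) / len(b)
            out.append(abs(pa - pb))
        return out

    obs = spread(tuple(range(n1)))
    combos = list(itertools.combinations(range(n), n1))
    per_level, overall = [], 0
    for j in range(len(levels)):
        per_level.append(sum(spread(c)[j] >= obs[j] - 1e-12 for c in combos) / len(combos))
    obs_max = max(obs)
    overall = sum(max(spread(c)) >= obs_max - 1e-12 for c in combos) / len(combos)
    return dict(zip(levels, per_level)), overall


class TestRandomization:
    def test_identical_groups_give_p_one(self):
        res = randomization_test(["a"] * 5 + ["b"] * 5, ["clumps"] * 10, B=100, seed=0)
        assert res["overall"].p_value == pytest.approx(1.0)

    def test_complete_separation_attains_minimum(self):
        res = randomization_test(
            ["a"] * 10 + ["b"] * 10, ["coccus"] * 10 + ["rod"] * 10, B=100_000, seed=0
        )
        # permutation minimum is 2/C(20,10) ~ 1.1e-5; the add-one MC bound applies
        assert res["overall"].p_value < 1e-4
        assert res["overall"].p_value >= 1.0 / (100_000 + 1)

    def test_reproducible_and_order_invariant(self, rng):
        labels = ["a"] * 8 + ["b"] * 8
        outcomes = list("xxyyzzxy") + list("yyzzxxyz")
        r1 = randomization_test(labels, outcomes, B=2000, seed=7)
        r2 = randomization_test(labels, outcomes, B=2000, seed=7)
        perm = rng.permutation(16)
        r3 = randomization_test(
            [labels[i] for i in perm], [outcomes[i] for i in perm], B=2000, seed=7
        )
        for key in r1["levels"]:
            assert r1["levels"][key].p_value == r2["levels"][key].p_value
            assert r1["levels"][key].p_value == r3["levels"][key].p_value

    def test_exact_enumeration_matches_brute_force(self):
        labels = ["a"] * 4 + ["b"] * 5
        outcomes = ["x", "x", "y", "z", "y", "y", "z", "z", "x"]
        res = randomization_test(labels, outcomes, exact=True)
        oracle_levels, oracle_overall = _exact_oracle(labels, outcomes)
        for lvl, p in oracle_levels.items():
            assert res["levels"][lvl].p_value == pytest.approx(p)
        assert res["overall"].p_value == pytest.approx(oracle_overall)

    def test_monte_carlo_consistent_with_exact(self):
        labels = ["a"] * 5 + ["b"] * 5
        outcomes = ["x", "y", "x", "x", "y", "y", "y", "x", "y", "y"]
        exact = randomization_test(labels, outcomes, exact=True)
        mc = randomization_test(labels, outcomes, B=40_000, seed=3)
        p_e, p_m = exact["overall"].p_value, mc["overall"].p_value
        assert abs(p_e - p_m) < 0.02

    def test_less_extreme_fraction_complements_p(self):
        res = randomization_test(
            ["a"] * 6 + ["b"] * 6, ["x"] * 4 + ["y"] * 2 + ["x"] * 2 + ["y"] * 4, B=5000, seed=1
        )
        ov = res["overall"]
        # ties at the observed statistic make these complements only approximately
        assert ov.extra["less_extreme"] <= 1.0 - (ov.p_value - 1.0 / 5001)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            randomization_test(["a"] * 4, ["x"] * 4, B=10, seed=0)

    def test_p_never_below_permutation_floor(self):
        res = randomization_test(["a", "a", "b", "b"], ["x", "x", "y", "y"], B=50, seed=0)
        assert res["overall"].p_value >= 1.0 / 51


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.04, 0.5]
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p) and np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
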