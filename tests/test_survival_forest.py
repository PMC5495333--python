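"""Random survival forest: splitting, OOB error, VIMP, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from lifelines.statistics import logrank_test as ll_logrank

from adgfs import (
    ForestConfig,
    SurvivalDataset,
    backward_select,
    grow_forest,
    harrell_c,
    oob_error,
    partial_dependence,
    vimp,
)
from adgfs.survival_forest import ensemble_mortality, logrank_statistic


def separable_data(seed=0, n=40):
    """Half fail early, half censored late; x separates them perfectly."""
    rng = np.random.default_rng(seed)
    x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    t = np.r_[rng.uniform(0.5, 2, n // 2), rng.uniform(8, 10, n // 2)]
    d = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(bool)
    return SurvivalDataset(pd.DataFrame({"x": x}), t, d)


def noise_data(seed, n=500, p=4):
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame({f"z{i}": rng.normal(size=n) for i in range(p)})
    t = rng.exponential(5, n)
    d = rng.uniform(size=n) < 0.7
    return SurvivalDataset(cov, t, d)


class TestHarrellC:
    def test_perfect_concordance(self):
        assert harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_brute_force_on_three_events(self):
        # comparable pairs (1,2),(1,3),(2,3); mortality (3,1,2) gets 2 right
        assert harrell_c([3, 1, 2], [1, 2, 3], [1, 1, 1]) == pytest.approx(2 / 3)

    def test_all_tied_predictions_are_half(self):
        assert harrell_c([5, 5, 5], [1, 2, 3], [1, 1, 1]) == 0.5

    def test_matches_pairwise_brute_force_with_censoring(self):
        rng = np.random.default_rng(2)
        n = 50
        m = rng.normal(size=n)
        t = rng.exponential(5, n)
        d = rng.uniform(size=n) < 0.6
        conc = ties = pairs = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if d[i] and (t[i] < t[j] or (t[i] == t[j] and not d[j])):
                    pairs += 1
                    conc += m[i] > m[j]
                    ties += m[i] == m[j]
        expected = (conc + 0.5 * ties) / pairs
        assert harrell_c(m, t, d) == pytest.approx(expected, abs=1e-12)

    def test_no_comparable_pairs_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c([1.0, 2.0], [5.0, 5.0], [0, 0])

    @given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    def test_invariant_under_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(7)
        m = rng.normal(size=30)
        t = rng.exponential(5, 30)
        d = rng.uniform(size=30) < 0.7
        base = harrell_c(m, t, d)
        assert harrell_c(scale * m + shift, t, d) == pytest.approx(base)


class TestLogrankSplit:
    def test_matches_lifelines_on_every_cutpoint_of_a_node(self):
        """Oracle equivalence on a 30-patient node, exhaustive cutpoints."""
        rng = np.random.default_rng(5)
        n = 30
        x = rng.normal(size=n)
        t = rng.exponential(4, n)
        d = rng.uniform(size=n) < 0.7
        for c in np.unique(x)[:-1]:
            g = x <= c
            if g.sum() == 0 or (~g).sum() == 0:
                continue
            z = logrank_statistic(t, d, g)
            ref = ll_logrank(t[g], t[~g], event_observed_A=d[g],
                             event_observed_B=d[~g])
            assert z**2 == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_restricted_best_never_beats_exhaustive(self):
        """nsplit-restricted split score <= exhaustive maximum."""
        rng = np.random.default_rng(8)
        n = 30
        x = rng.normal(size=n)
        t = rng.exponential(4, n)
        d = rng.uniform(size=n) < 0.8
        exhaustive = max(
            abs(logrank_statistic(t, d, x <= c)) for c in np.unique(x)[:-1]
        )
        for trial in range(10):
            cuts = rng.choice(np.unique(x)[:-1], size=3, replace=False)
            restricted = max(abs(logrank_statistic(t, d, x <= c)) for c in cuts)
            assert restricted <= exhaustive + 1e-12


class TestGrowForest:
    def test_separable_covariate_wins_every_root(self):
        data = separable_data()
        model = grow_forest(data, ForestConfig(n_trees=50, seed=1))
        assert all(tree.nodes[0].var == 0 for tree in model.trees)

    def test_separable_data_low_error(self):
        # continuous risk gradient: deeper trees order patients within groups
        rng = np.random.default_rng(3)
        n = 120
        x = rng.uniform(0, 1, n)
        t = np.exp(3 * (1 - x)) * rng.lognormal(0, 0.05, n) / 5
        data = SurvivalDataset(pd.DataFrame({"x": x}), t, np.ones(n, bool))
        model = grow_forest(data, ForestConfig(n_trees=100, seed=1))
        assert oob_error(model, data) < 0.1

    def test_oob_fraction_near_e_inverse(self):
        data = noise_data(0, n=100)
        model = grow_forest(data, ForestConfig(n_trees=500, seed=2))
        assert model.mean_oob_fraction() == pytest.approx(0.368, abs=0.02)

    def test_inbag_multiset_size_is_n(self):
        data = noise_data(1, n=80)
        model = grow_forest(data, ForestConfig(n_trees=20, seed=0))
        for tree in model.trees:
            assert tree.inbag_counts.sum() == 80

    def test_deterministic_under_seed(self):
        data = noise_data(2, n=100)
        a = grow_forest(data, ForestConfig(n_trees=30, seed=9))
        b = grow_forest(data, ForestConfig(n_trees=30, seed=9))
        np.testing.assert_array_equal(
            ensemble_mortality(a, data), ensemble_mortality(b, data)
        )

    def test_all_censored_data_is_growth_error(self):
        data = SurvivalDataset(pd.DataFrame({"x": [1.0, 2, 3, 4]}),
                               [1.0, 2, 3, 4], [0, 0, 0, 1])
        with pytest.raises(ValueError, match="2 events"):
            grow_forest(data, ForestConfig(n_trees=5, seed=0))


class TestOobErrorAndVimp:
    def test_error_plus_concordance_is_one(self):
        data = noise_data(3, n=150)
        model = grow_forest(data, ForestConfig(n_trees=50, seed=4))
        mort = ensemble_mortality(model, data)
        c = harrell_c(mort, data.time, data.event)
        assert oob_error(model, data) == pytest.approx(1 - c, abs=1e-12)

    def test_pure_noise_error_near_half(self):
        data = noise_data(4, n=500)
        model = grow_forest(data, ForestConfig(n_trees=100, seed=5))
        assert oob_error(model, data) == pytest.approx(0.5, abs=0.05)

    def test_noise_vimp_near_zero_and_unused_variable_exactly_zero(self):
        """Null VIMP distribution centers on zero; a variable absent from
        every split scores exactly zero."""
        vals = []
        for s in (5, 15, 25):
            data = noise_data(s, n=500)
            cov = data.covariates.copy()
            cov["const"] = 1.0  # never selected by any split
            data = SurvivalDataset(cov, data.time, data.event)
            model = grow_forest(data, ForestConfig(n_trees=100, seed=s + 1))
            table = vimp(model, data, seed=s + 2)
            assert table["const"] == 0.0
            vals += [table[v] for v in data.variables if v != "const"]
        vals = np.array(vals)
        # single-dataset VIMPs inherit the c-index's sampling noise (~0.02-0.05
        # at n=500); the null is centered, not pointwise tiny
        assert abs(vals.mean()) < 0.015
        assert np.max(np.abs(vals)) < 0.08

    def test_informative_variable_dominates_vimp(self):
        data = separable_data(n=60)
        cov = data.covariates.copy()
        cov["noise"] = np.random.default_rng(0).normal(size=60)
        data = SurvivalDataset(cov, data.time, data.event)
        model = grow_forest(data, ForestConfig(n_trees=100, seed=8))
        table = vimp(model, data, seed=9)
        assert table.variables[0] == "x"
        assert table["x"] > 0.1


class TestBackwardSelect:
    def test_single_variable_trace(self):
        data = separable_data()
        sel, trace = backward_select(data, ForestConfig(n_trees=30, seed=0))
        assert sel == ["x"] and len(trace) == 1

    def test_recovers_informative_pair_against_noise(self):
        rng = np.random.default_rng(12)
        n = 400
        cov = pd.DataFrame({
            "a": rng.normal(size=n),
            "b": (rng.uniform(size=n) < 0.4).astype(int),
            "n1": rng.normal(size=n),
            "n2": rng.normal(size=n),
            "n3": (rng.uniform(size=n) < 0.5).astype(int),
        })
        lam = 0.08 * np.exp(1.2 * cov["a"] + 1.5 * cov["b"])
        t = rng.exponential(1 / lam)
        c = rng.uniform(0, 15, n)
        data = SurvivalDataset(cov, np.minimum(t, c), t <= c)
        sel, _ = backward_select(data, ForestConfig(n_trees=120, mtry=1, seed=1))
        assert set(sel) == {"a", "b"}

    def test_no_signal_raises(self):
        # constant covariates are never split on, so every VIMP is exactly 0
        rng = np.random.default_rng(6)
        cov = pd.DataFrame({"c1": np.ones(60), "c2": np.zeros(60)})
        data = SurvivalDataset(cov, rng.exponential(5, 60),
                               rng.uniform(size=60) < 0.7)
        with pytest.raises(ValueError, match="positive VIMP"):
            backward_select(data, ForestConfig(n_trees=20, seed=0))


class TestPartialDependence:
    def test_zero_effect_variable_is_flat(self):
        # shallow trees (large terminal nodes) so the ensemble estimates the
        # marginal effect rather than memorized in-bag noise
        data = noise_data(7, n=400, p=2)
        model = grow_forest(
            data, ForestConfig(n_trees=150, min_terminal_events=25, seed=3)
        )
        pdp = partial_dependence(model, data, "z0",
                                 np.linspace(-1.5, 1.5, 5), horizon=5.0)
        assert pdp["survival"].max() - pdp["survival"].min() < 0.06

    def test_monotone_hazard_gives_decreasing_survival(self):
        rng = np.random.default_rng(13)
        n = 300
        age = rng.uniform(20, 80, n)
        lam = 0.02 * np.exp(0.05 * (age - 40))
        t = rng.exponential(1 / lam)
        c = rng.uniform(0, 15, n)
        data = SurvivalDataset(pd.DataFrame({"age": age, "z": rng.normal(size=n)}),
                               np.minimum(t, c), t <= c)
        model = grow_forest(data, ForestConfig(n_trees=100, seed=4))
        pdp = partial_dependence(model, data, "age",
                                 np.array([30.0, 45.0, 60.0, 75.0]), horizon=10.0)
        s = pdp["survival"].to_numpy()
        assert s[0] > s[-1]
        assert np.all(np.diff(s) <= 0.02)  # monotone up to MC wiggle

    def test_extrapolation_flagged(self):
        data = noise_data(8, n=100, p=2)
        model = grow_forest(data, ForestConfig(n_trees=20, seed=5))
        with pytest.warns(UserWarning, match="outside observed range"):
            pdp = partial_dependence(model, data, "z0", [99.0], horizon=5.0)
        assert pdp["extrapolated"].iloc[0]
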