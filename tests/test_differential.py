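"""MWU/BH testing, bootstrap stability, LASSO selection and DMP intersection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata

from gctmethyl.differential import (
    DmpSet,
    bh_adjust,
    bootstrap_validate,
    delta_median,
    intersect_dmps,
    lasso_state_selection,
    mwu_bh,
    mwu_pvalues,
    recommended_delta_m,
    evaluate_features,
)


def exact_mwu_oracle(a, b):
    """Two-sided p by full enumeration of group labelings."""
    pooled = np.r_[a, b]
    na = len(a)
    ranks = rankdata(pooled)
    u_of = lambda idx: ranks[list(idx)].sum() - na * (na + 1) / 2
    u_obs = u_of(range(na))
    us = np.array([u_of(c) for c in itertools.combinations(range(len(pooled)), na)])
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestMwu:
    def test_known_example(self):
        # U = 0; 2 of the C(6,3)=20 labelings are as extreme
        p = mwu_pvalues(np.array([[1.0, 2, 3]]), np.array([[4.0, 5, 6]]))
        assert p[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_tied_groups_not_significant(self):
        p = mwu_pvalues(np.array([[1.0, 1, 1]]), np.array([[1.0, 1, 1]]))
        assert p[0] == 1.0

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 6), (5, 5), (8, 7), (8, 8)])
    def test_exact_matches_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(4):
            a = rng.normal(size=na)
            b = rng.normal(0.4, 1.2, size=nb)
            assert mwu_pvalues(a[None], b[None])[0] == pytest.approx(
                exact_mwu_oracle(a, b), abs=1e-12
            )

    def test_asymptotic_close_to_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 30))
        b = rng.normal(0.3, 1, size=(5, 25))
        mine = mwu_pvalues(a, b)
        ref = mannwhitneyu(a, b, axis=1, method="asymptotic").pvalue
        np.testing.assert_allclose(mine, ref, rtol=1e-10)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mwu_pvalues(np.empty((1, 0)), np.ones((1, 3)))


class TestBh:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.005, 0.01, 0.03, 0.04])), [0.02, 0.02, 0.04, 0.04]
        )

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    def test_matches_step_up_formula(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        manual = np.empty(m)
        running = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            rank = m - rank_from_last
            running = min(running, p[idx] * m / rank)
            manual[idx] = running
        np.testing.assert_allclose(adj, manual, atol=1e-12)
        assert np.all(adj >= p - 1e-15)


class TestBootstrap:
    def _frame(self, a, b):
        cols_a = [f"a{i}" for i in range(a.shape[1])]
        cols_b = [f"b{i}" for i in range(b.shape[1])]
        return (
            pd.DataFrame(np.c_[a, b], columns=cols_a + cols_b),
            cols_a,
            cols_b,
        )

    def test_complete_separation_full_support(self):
        rng = np.random.default_rng(0)
        f, ca, cb = self._frame(rng.normal(-2, 0.1, (3, 10)), rng.normal(2, 0.1, (3, 10)))
        support = bootstrap_validate(f, ca, cb, seed=1)
        assert (support == 1.0).all()

    def test_null_feature_low_support(self):
        rng = np.random.default_rng(1)
        f, ca, cb = self._frame(rng.normal(size=(20, 12)), rng.normal(size=(20, 12)))
        support = bootstrap_validate(f, ca, cb, seed=2)
        assert support.mean() <= 0.05  # BH within replicates keeps support near zero

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        f, ca, cb = self._frame(rng.normal(size=(5, 8)), rng.normal(1, 1, (5, 8)))
        s1 = bootstrap_validate(f, ca, cb, seed=9)
        s2 = bootstrap_validate(f, ca, cb, seed=9)
        pd.testing.assert_series_equal(s1, s2)

    def test_degenerate_group_errors(self):
        f, ca, cb = self._frame(np.zeros((2, 1)), np.ones((2, 5)))
        with pytest.raises(ValueError):
            bootstrap_validate(f, ca, cb)


class TestTestFeatures:
    def test_delta_threshold_is_strict(self):
        rng = np.random.default_rng(3)
        # complete separation but |ΔM| = 0.89: must fail the > 0.9 rule
        a = rng.normal(0.0, 0.01, (1, 10))
        b = a + 0.89
        f = pd.DataFrame(np.c_[a, b], columns=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)])
        res = evaluate_features(f, [f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)], seed=0)
        row = res.iloc[0]
        assert row["significant"] and row["support"] >= 0.95
        assert not row["passes"]

    def test_planted_block_passes_and_null_does_not(self):
        rng = np.random.default_rng(4)
        n = 200
        a = rng.normal(0, 0.5, (n, 12))
        b = rng.normal(0, 0.5, (n, 12))
        b[:10] += 3.0  # planted ΔM = 3
        f = pd.DataFrame(np.c_[a, b], columns=[f"a{i}" for i in range(12)] + [f"b{i}" for i in range(12)])
        res = evaluate_features(f, [f"a{i}" for i in range(12)], [f"b{i}" for i in range(12)], seed=0)
        assert res["passes"][:10].all()
        assert res["direction"][:10].eq("hyperB").all()
        assert res["passes"][10:].sum() == 0


class TestLasso:
    def _medians(self, X):
        return pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])],
                            columns=[f"x{i}" for i in range(X.shape[1])])

    def test_separating_state_selected_among_noise(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.zeros(20), np.ones(20)]
        X = rng.normal(size=(20, 40))
        X[7] = np.where(y == 1, 2.0, -2.0) + rng.normal(0, 0.3, 40)
        sm = self._medians(X)
        sel, coef = lasso_state_selection(
            sm, [f"x{i}" for i in range(20, 40)], [f"x{i}" for i in range(20)], seed=0
        )
        assert sel == ["s7"]
        assert coef.drop("s7").abs().max() < 1e-8

    def test_strong_regularization_limit_selects_nothing(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 20))
        sm = self._medians(X)
        sel, _ = lasso_state_selection(
            sm, [f"x{i}" for i in range(10)], [f"x{i}" for i in range(10, 20)],
            seed=0, lambda_min_ratio=0.999999, n_lambda=2,  # stay at λ_max
        )
        assert sel == []

    def test_permuted_labels_rarely_select(self):
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(10):
            X = rng.normal(size=(8, 24))
            sm = self._medians(X)
            cols = list(sm.columns)
            perm = rng.permutation(cols)
            sel, _ = lasso_state_selection(sm, list(perm[:12]), list(perm[12:]), seed=rep)
            hits += len(sel) > 0
        assert hits <= 2

    def test_identical_labels_error(self):
        X = np.random.default_rng(0).normal(size=(3, 10))
        sm = self._medians(X)
        with pytest.raises(ValueError):
            lasso_state_selection(sm, list(sm.columns), [], seed=0)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 30))
        X[2] = np.r_[np.full(15, -1.0), np.full(15, 1.0)] + rng.normal(0, 0.5, 30)
        sm = self._medians(X)
        ca, cb = [f"x{i}" for i in range(15)], [f"x{i}" for i in range(15, 30)]
        r1 = lasso_state_selection(sm, ca, cb, seed=4)
        r2 = lasso_state_selection(sm, ca, cb, seed=4)
        assert r1[0] == r2[0]
        pd.testing.assert_series_equal(r1[1], r2[1])


class TestIntersect:
    def test_disjoint_routes_empty(self):
        d = intersect_dmps(
            {"hyperA": {"p1"}}, {"hyperA": {"p2"}}, {"hyperA": {"p3"}}, ("A", "B")
        )
        assert d.hyper_a == set() and d.hyper_b == set()

    def test_nested_routes_equal_probe_route(self):
        probe = {"hyperA": {"p1", "p2"}, "hyperB": set()}
        segment = {"hyperA": {"p1", "p2", "p3"}, "hyperB": set()}
        state = {"hyperA": {"p1", "p2", "p3", "p4"}, "hyperB": set()}
        d = intersect_dmps(state, segment, probe, ("A", "B"))
        assert d.hyper_a == probe["hyperA"]

    def test_universe_mismatch_errors(self):
        with pytest.raises(ValueError, match="universe"):
            intersect_dmps(
                {"hyperA": {"p9"}}, {"hyperA": {"p9"}}, {"hyperA": {"p9"}},
                ("A", "B"), universe={"p1"},
            )

    def test_direction_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(6)
        n = 300
        m = pd.DataFrame(
            np.c_[rng.normal(0, 0.5, (n, 10)), rng.normal(0, 0.5, (n, 10))],
            index=[f"cg{i}" for i in range(n)],
            columns=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
        )
        m.iloc[:8, :10] += 3.0
        m.iloc[8:16, 10:] += 3.0
        ca, cb = [f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)]

        def dmps(c1, c2, comparison):
            res = evaluate_features(m, c1, c2, seed=0)
            sets = {
                d: set(res.index[(res["passes"]) & (res["direction"] == d)])
                for d in ("hyperA", "hyperB")
            }
            return intersect_dmps(sets, sets, sets, comparison)

        ab = dmps(ca, cb, ("A", "B"))
        ba = dmps(cb, ca, ("B", "A"))
        assert ab.hyper_a == ba.hyper_b and ab.hyper_b == ba.hyper_a
        assert ab.hyper_a and ab.hyper_b  # both directions exercised

    def test_dm_min_monotonicity(self):
        rng = np.random.default_rng(7)
        n = 100
        m = pd.DataFrame(
            np.c_[rng.normal(0, 0.3, (n, 8)), rng.normal(0, 0.3, (n, 8))],
            index=[f"cg{i}" for i in range(n)],
            columns=[f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)],
        )
        m.iloc[:30, :8] += rng.uniform(0.5, 4.0, size=(30, 1))
        ca, cb = [f"a{i}" for i in range(8)], [f"b{i}" for i in range(8)]
        previous = None
        for dm_min in (0.4, 0.9, 1.4, 2.5):
            res = evaluate_features(m, ca, cb, dm_min=dm_min, seed=0)
            passing = set(res.index[res["passes"]])
            if previous is not None:
                assert passing <= previous
            previous = passing

    def test_dmpset_disjointness_enforced(self):
        with pytest.raises(ValueError):
            DmpSet(("A", "B"), {"p1"}, {"p1"})


def test_recommended_delta_m_is_midpoint_of_range():
    assert recommended_delta_m() == pytest.approx(0.9, abs=1e-12)
    assert recommended_delta_m(0.2, 1.0) == pytest.approx(0.6, abs=1e-12)


def test_delta_median_sign_convention():
    m = pd.DataFrame([[1.0, 2.0, 5.0, 6.0]], columns=["a1", "a2", "b1", "b2"])
    assert delta_median(m, ["a1", "a2"], ["b1", "b2"]).iloc[0] == -4.0
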