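"""HMM segmentation: likelihood/Viterbi oracles, EM behaviour, segments."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from gctmethyl.annotation import ProbeTable
from gctmethyl.hmm import (
    HmmModel,
    fit_hmm,
    forward_loglik,
    select_k,
    segment_medians,
    state_medians,
    viterbi_segment,
)


def random_model(k: int, d: int, rng) -> HmmModel:
    pi = rng.dirichlet(np.ones(k))
    A = rng.dirichlet(np.ones(k), size=k)
    return HmmModel(
        k=k,
        pi=pi,
        transmat=A,
        means=rng.normal(0, 2, size=(k, d)),
        variances=rng.uniform(0.2, 2.0, size=(k, d)),
        train_loglik=0.0,
        seed=0,
    )


def all_path_logliks(model: HmmModel, X: np.ndarray) -> np.ndarray:
    """Log-probability of every state path (vectorized brute force)."""
    k, T = model.k, len(X)
    paths = np.stack(np.unravel_index(np.arange(k**T), (k,) * T)).T  # (k^T, T)
    emis = np.array(
        [
            [norm.logpdf(X[t], model.means[s], np.sqrt(model.variances[s])).sum() for s in range(k)]
            for t in range(T)
        ]
    )  # (T, k)
    lp = np.log(model.pi)[paths[:, 0]] + emis[0, paths[:, 0]]
    for t in range(1, T):
        lp += np.log(model.transmat)[paths[:, t - 1], paths[:, t]] + emis[t, paths[:, t]]
    return lp


def probes_for(n: int, chrom="1") -> ProbeTable:
    return ProbeTable(
        pd.DataFrame(
            {
                "probe_id": [f"cg{i:04d}" for i in range(n)],
                "chrom": [chrom] * n,
                "pos": np.arange(1, n + 1) * 100,
                "strand": ["+"] * n,
                "gene_symbols": ["G"] * n,
                "tss_distance_class": ["none"] * n,
                "region_classes": ["GENE.BODY"] * n,
                "island": [False] * n,
                "repeat_class": ["none"] * n,
                "mir": [False] * n,
                "snrna": [False] * n,
            }
        )
    )


class TestForwardAndViterbiOracles:
    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    @pytest.mark.parametrize("T", [1, 3, 5, 8])
    def test_forward_equals_path_enumeration(self, k, T):
        rng = np.random.default_rng(100 * k + T)
        model = random_model(k, d=2, rng=rng)
        X = rng.normal(0, 2, size=(T, 2))
        brute = logsumexp(all_path_logliks(model, X))
        fwd = forward_loglik(model, X, [(0, T)])
        assert abs(fwd - brute) / abs(brute) < 1e-10

    @pytest.mark.parametrize("k", [2, 3, 4])
    @pytest.mark.parametrize("T", [3, 6, 8])
    def test_viterbi_equals_argmax_over_paths(self, k, T):
        rng = np.random.default_rng(7 * k + T)
        model = random_model(k, d=1, rng=rng)
        X = rng.normal(0, 2, size=(T, 1))
        lp = all_path_logliks(model, X)
        best = np.stack(np.unravel_index(np.arange(k**T), (k,) * T)).T[np.argmax(lp)]
        segs = viterbi_segment(model, X, probes_for(T))
        decoded = np.concatenate([[s.state] * s.n_probes for s in segs])
        assert np.array_equal(decoded, best)


class TestFitHmm:
    def test_k1_closed_form_loglik(self):
        rng = np.random.default_rng(0)
        X = rng.normal(1.0, 1.5, size=(50, 3))
        model = fit_hmm(X, [(0, 50)], k=1, seed=0, n_restarts=1, var_floor=1e-6)
        mu, var = X.mean(axis=0), X.var(axis=0)
        expected = norm.logpdf(X, mu, np.sqrt(var)).sum()
        assert model.train_loglik == pytest.approx(expected, rel=1e-8)

    def test_em_loglik_nondecreasing(self):
        rng = np.random.default_rng(42)
        X = np.r_[rng.normal(-1, 1, (60, 2)), rng.normal(2, 1, (60, 2))]
        model = fit_hmm(X, [(0, 120)], k=3, seed=1, n_restarts=1)
        h = np.asarray(model.loglik_history)
        assert np.all(np.diff(h) >= -1e-8)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 2))
        m1 = fit_hmm(X, [(0, 80)], k=2, seed=5)
        m2 = fit_hmm(X, [(0, 80)], k=2, seed=5)
        np.testing.assert_array_equal(m1.means, m2.means)
        assert m1.train_loglik == m2.train_loglik

    def test_input_validation(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            fit_hmm(X, [(0, 5)], k=9)
        X2 = X.copy()
        X2[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_hmm(X2, [(0, 5)], k=1)

    def test_parameter_recovery_three_states(self):
        """Well-separated 3-state chain: means within 0.1, accuracy >= 95%."""
        rng = np.random.default_rng(11)
        true_means = np.array([[-4.0, -4.0], [0.0, 0.0], [4.0, 4.0]])
        A = np.full((3, 3), 0.05)
        np.fill_diagonal(A, 0.9)
        states = [0]
        for _ in range(2499):
            states.append(rng.choice(3, p=A[states[-1]]))
        states = np.array(states)
        X = true_means[states] + rng.normal(0, 0.4, size=(2500, 2))
        model = fit_hmm(X, [(0, 2500)], k=3, seed=0)
        order = np.argsort(model.means[:, 0])
        np.testing.assert_allclose(model.means[order], true_means, atol=0.1)
        segs = viterbi_segment(model, X, probes_for(2500))
        decoded = np.concatenate([[s.state] * s.n_probes for s in segs])
        relabel = {order[i]: i for i in range(3)}
        acc = np.mean([relabel[s] for s in decoded] == states)
        assert acc >= 0.95


class TestSelectK:
    def test_elbow_at_three_planted_states(self):
        rng = np.random.default_rng(21)
        means = np.array([[-4.0], [0.0], [4.0]])
        states = rng.integers(0, 3, size=900)
        X = means[states] + rng.normal(0, 0.3, size=(900, 1))
        k_sel, curve = select_k(X, [(0, 900)], [1, 2, 3, 4, 5], seed=0, max_iter=100)
        assert k_sel == 3
        assert curve == sorted(curve)  # best-of-restarts keeps the curve monotone

    def test_singleton_grid(self):
        X = np.random.default_rng(0).normal(size=(30, 1))
        k_sel, curve = select_k(X, [(0, 30)], [1], seed=0)
        assert k_sel == 1 and len(curve) == 1

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            select_k(np.zeros((10, 1)), [(0, 10)], [], seed=0)


class TestSegments:
    def test_identical_probes_single_segment_per_chromosome(self):
        X = np.tile([[0.5, -0.5]], (40, 1))
        model = fit_hmm(X, [(0, 20), (20, 40)], k=1, seed=0)
        pt = ProbeTable(
            pd.concat([probes_for(20, "1").df, probes_for(20, "2").df.assign(
                probe_id=[f"cgB{i:04d}" for i in range(20)])])
        )
        segs = viterbi_segment(model, X, pt)
        assert len(segs) == 2
        assert {s.chrom for s in segs} == {"1", "2"}

    def test_alternating_states_give_unit_segments(self):
        model = HmmModel(
            k=2,
            pi=np.array([0.5, 0.5]),
            transmat=np.array([[0.5, 0.5], [0.5, 0.5]]),
            means=np.array([[-3.0], [3.0]]),
            variances=np.array([[0.1], [0.1]]),
            train_loglik=0.0,
            seed=0,
        )
        X = np.array([[-3.0], [3.0], [-3.0], [3.0], [-3.0]])
        segs = viterbi_segment(model, X, probes_for(5))
        assert [s.n_probes for s in segs] == [1, 1, 1, 1, 1]

    def test_segments_partition_probes(self, small_cohort):
        m = small_cohort.matrix.m
        model = fit_hmm(m, small_cohort.probes.chrom_bounds(), k=3, seed=0, n_restarts=1,
                        max_iter=50)
        segs = viterbi_segment(model, m, small_cohort.probes)
        seen = [p for s in segs for p in s.probe_ids]
        assert len(seen) == len(small_cohort.probes)
        assert set(seen) == set(small_cohort.probes.probe_ids)

    def test_sample_count_mismatch_errors(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        model = fit_hmm(X, [(0, 10)], k=1, seed=0)
        with pytest.raises(ValueError):
            viterbi_segment(model, rng.normal(size=(10, 3)), probes_for(10))


class TestMedians:
    def test_state_median_simple(self):
        X = np.array([[-1.0], [0.0], [1.0]])
        model = fit_hmm(X, [(0, 3)], k=1, seed=0)
        segs = viterbi_segment(model, X, probes_for(3))
        med = state_medians(segs, X)
        assert med.loc[0, 0] == 0.0

    def test_medians_match_bruteforce(self, small_cohort):
        m = small_cohort.matrix.m
        model = fit_hmm(m, small_cohort.probes.chrom_bounds(), k=3, seed=1, n_restarts=1,
                        max_iter=50)
        segs = viterbi_segment(model, m, small_cohort.probes)
        arr = m.to_numpy()
        med = state_medians(segs, arr)
        for state in med.index:
            rows = np.concatenate(
                [np.arange(s.row_slice.start, s.row_slice.stop) for s in segs if s.state == state]
            )
            np.testing.assert_allclose(med.loc[state].to_numpy(), np.median(arr[rows], axis=0))
        seg_med = segment_medians(segs, arr)
        np.testing.assert_allclose(seg_med[0], np.median(arr[segs[0].row_slice], axis=0))

    def test_sex_separating_state_concentrates_x_probes(self):
        """With a female group, one state should be nearly X-exclusive,
        mirroring the sex-separating state seen in real segmentations."""
        from tests.conftest import small_spec
        from gctmethyl.synthetic import GroupSpec, generate_cohort

        spec = small_spec(
            groups=(GroupSpec("M1", 6, "M", "bimodal"), GroupSpec("F1", 6, "F", "bimodal")),
            n_probes_per_chrom=(("1", 800), ("X", 800)),
            planted_dmrs=(),
        )
        co = generate_cohort(spec, seed=3)
        m = co.matrix.m
        model = fit_hmm(m, co.probes.chrom_bounds(), k=4, seed=0, n_restarts=2, max_iter=100)
        segs = viterbi_segment(model, m, co.probes)
        frac_x = {}
        for state in range(model.k):
            ids = [p for s in segs if s.state == state for p in s.probe_ids]
            if not ids:
                continue
            on_x = co.probes.df.set_index("probe_id").loc[ids, "chrom"] == "X"
            frac_x[state] = float(np.mean(on_x))
        assert max(frac_x.values()) > 0.95
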