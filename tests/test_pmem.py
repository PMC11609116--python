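import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elscape import pmem
from elscape.synth import sample_pmem_states


# ---------------------------------------------------------------------------
# state coding
# ---------------------------------------------------------------------------

class TestStateCoding:
    def test_all_minus_one_is_index_zero(self):
        assert pmem.encode_states(-np.ones(7, dtype=int))[0] == 0
        assert pmem.state_string(0, 7) == "0000000"

    def test_display_convention_first_channel_leftmost(self):
        spins = np.array([1, -1, -1, -1, -1, -1, -1])
        idx = int(pmem.encode_states(spins)[0])
        assert idx == 64
        assert pmem.state_string(idx, 7) == "1000000"

    def test_complement_indices_sum_to_127(self):
        a = int("0000111", 2)
        b = int("1111000", 2)
        assert a + b == 127
        assert np.array_equal(
            pmem.decode_state(a, 7), -pmem.decode_state(b, 7)
        )

    def test_bijection(self):
        strings = {pmem.state_string(i, 7) for i in range(128)}
        assert len(strings) == 128
        for i in range(128):
            assert pmem.encode_states(pmem.decode_state(i, 7))[0] == i

    def test_out_of_range_index(self):
        with pytest.raises(ValueError):
            pmem.decode_state(128, 7)

    def test_non_spin_entries_rejected(self):
        with pytest.raises(ValueError):
            pmem.encode_states(np.array([0, 1, 1]))


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

class TestBinarize:
    def test_two_point_case(self):
        series = pmem.binarize(np.array([[1.0], [3.0]]))
        assert series.spins.tolist() == [[-1], [1]]

    def test_constant_channel_is_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pmem.binarize(np.full((10, 2), 5.0))

    def test_threshold_is_per_channel_mean(self, rng):
        x = rng.normal(size=(50, 3)) + np.array([10.0, -5.0, 0.0])
        series = pmem.binarize(x)
        expected = np.where(x > x.mean(axis=0), 1, -1)
        assert np.array_equal(series.spins, expected)

    def test_tie_goes_to_minus_one(self):
        # strict inequality at the threshold
        x = np.array([[0.0], [0.0], [3.0]])  # mean 1.0; no sample equals mean
        x2 = np.array([[1.0], [1.0], [1.0], [5.0]])  # mean 2.0
        assert pmem.binarize(x).spins.ravel().tolist() == [-1, -1, 1]
        assert pmem.binarize(x2).spins.ravel().tolist() == [-1, -1, -1, 1]


# ---------------------------------------------------------------------------
# empirical statistics
# ---------------------------------------------------------------------------

class TestEmpiricalStats:
    def test_counting(self):
        a = [1, 1, 1]
        b = [-1, 1, -1]
        c = [1, -1, -1]
        series = pmem.BinaryStateSeries(np.array([a, a, b, c]))
        stats = pmem.empirical_stats(series)
        ia, ib, ic = (int(pmem.encode_states(np.array(s))[0]) for s in (a, b, c))
        assert stats.probs[ia] == 0.5
        assert stats.probs[ib] == 0.25
        assert stats.probs[ic] == 0.25
        assert stats.probs.sum() == 1.0

    def test_single_state(self):
        s = np.array([[1, -1, 1]])
        stats = pmem.empirical_stats(pmem.BinaryStateSeries(np.repeat(s, 5, axis=0)))
        idx = int(pmem.encode_states(s)[0])
        assert stats.probs[idx] == 1.0
        assert np.array_equal(stats.cooc, np.outer(s[0], s[0]))

    def test_matches_naive_loops(self, rng):
        spins = rng.choice([-1, 1], size=(200, 4))
        stats = pmem.empirical_stats(pmem.BinaryStateSeries(spins))
        f = spins.shape[0]
        act = np.array([sum(spins[t, m] for t in range(f)) / f for m in range(4)])
        cooc = np.array(
            [
                [sum(spins[t, m] * spins[t, n] for t in range(f)) / f for n in range(4)]
                for m in range(4)
            ]
        )
        np.fill_diagonal(cooc, 1.0)
        assert np.allclose(stats.act, act)
        assert np.allclose(stats.cooc, cooc)


# ---------------------------------------------------------------------------
# the Boltzmann model
# ---------------------------------------------------------------------------

class TestBoltzmann:
    def test_normalization(self, random_model):
        h, J = random_model
        assert abs(pmem.boltzmann(h, J).sum() - 1.0) < 1e-12

    def test_gauge_invariance(self, random_model):
        """Adding a constant to all energies leaves P unchanged."""
        h, J = random_model
        p = pmem.boltzmann(h, J)
        e = pmem.energies(h, J) + 123.4
        w = np.exp(-(e - e.min()))
        assert np.allclose(p, w / w.sum(), atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_normalization_property(self, seed):
        rng = np.random.default_rng(seed)
        c = int(rng.integers(2, 7))
        h = rng.normal(0, 1, c)
        J = rng.normal(0, 1, (c, c))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 0.0)
        assert abs(pmem.boltzmann(h, J).sum() - 1.0) < 1e-12


class TestIndependentMem:
    def test_zero_activation_gives_uniform(self):
        stats = pmem.stats_from_distribution(np.full(128, 1 / 128))
        model = pmem.fit_independent_mem(stats)
        assert np.allclose(model.h, 0.0)
        assert np.allclose(model.probs, 1 / 128)

    def test_inverse_identity(self):
        probs = pmem.boltzmann(np.full(3, 0.5), np.zeros((3, 3)))
        stats = pmem.stats_from_distribution(probs)
        model = pmem.fit_independent_mem(stats)
        assert np.allclose(model.h, 0.5, atol=1e-12)

    def test_model_moments_match_activations(self, rng):
        act = rng.uniform(-0.8, 0.8, 6)
        h = np.arctanh(act)
        stats = pmem.stats_from_distribution(pmem.boltzmann(h, np.zeros((6, 6))))
        model = pmem.fit_independent_mem(stats)
        act_mod, _ = model.model_moments()
        assert np.allclose(act_mod, act, atol=1e-10)

    def test_saturated_channel_is_error(self):
        spins = np.ones((5, 3), dtype=int)
        spins[:, 1] = [-1, 1, -1, 1, -1]
        spins[:, 2] = [-1, 1, -1, 1, 1]
        stats = pmem.empirical_stats(pmem.BinaryStateSeries(spins))
        with pytest.raises(ValueError, match="saturated"):
            pmem.fit_independent_mem(stats)


class TestFitPmem:
    def test_null_model_recovery(self):
        series = sample_pmem_states(np.zeros(5), np.zeros((5, 5)), 100_000, seed=1)
        model = pmem.fit_pmem(pmem.empirical_stats(series), mode="pl")
        assert np.abs(model.h).max() < 0.05
        assert np.abs(model.J).max() < 0.05

    def test_exact_mode_self_consistency(self, random_model):
        h, J = random_model
        stats = pmem.stats_from_distribution(pmem.boltzmann(h, J))
        model = pmem.fit_pmem(stats, mode="exact", tol=1e-8)
        assert np.abs(model.h - h).max() < 1e-4
        assert np.abs(model.J - J).max() < 1e-4

    def test_exact_mode_moment_match(self, rng):
        spins = rng.choice([-1, 1], size=(400, 5))
        stats = pmem.empirical_stats(pmem.BinaryStateSeries(spins))
        model = pmem.fit_pmem(stats, mode="exact", tol=1e-8)
        act_mod, cooc_mod = model.model_moments()
        assert np.abs(act_mod - stats.act).max() < 1e-6
        assert np.abs(cooc_mod - stats.cooc).max() < 1e-6

    def test_parameter_recovery_both_modes(self, rng):
        c = 6
        h = rng.uniform(-1, 1, c)
        J = rng.uniform(-1, 1, (c, c))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 0.0)
        series = sample_pmem_states(h, J, 100_000, seed=2)
        stats = pmem.empirical_stats(series)
        pl = pmem.fit_pmem(stats, mode="pl")
        ex = pmem.fit_pmem(stats, mode="exact")
        for model in (pl, ex):
            assert np.sqrt(np.mean((model.h - h) ** 2)) <= 0.1
            assert np.sqrt(np.mean((model.J - J) ** 2)) <= 0.1
        # the two estimators agree within sampling error
        assert np.abs(pl.h - ex.h).max() <= 0.05
        assert np.abs(pl.J - ex.J).max() <= 0.05

    def test_symmetric_zero_diagonal(self, rng):
        spins = rng.choice([-1, 1], size=(300, 4))
        model = pmem.fit_pmem(pmem.BinaryStateSeries(spins), mode="pl")
        assert np.allclose(model.J, model.J.T)
        assert np.allclose(np.diag(model.J), 0.0)

    def test_refuses_large_c(self):
        with pytest.raises(ValueError, match="2\\^13"):
            pmem.fit_pmem(
                pmem.BinaryStateSeries(np.ones((2, 13), dtype=int)), mode="exact"
            )

    def test_non_convergence_flagged(self, rng):
        spins = rng.choice([-1, 1], size=(300, 4))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            model = pmem.fit_pmem(
                pmem.BinaryStateSeries(spins), mode="pl", max_iter=3
            )
        assert not model.converged


# ---------------------------------------------------------------------------
# accuracy index
# ---------------------------------------------------------------------------

class TestAccuracyIndex:
    def test_r_is_one_for_exact_boltzmann(self, random_model):
        h, J = random_model
        probs = pmem.boltzmann(h, J)
        stats = pmem.stats_from_distribution(probs)
        pairwise = pmem.fit_pmem(stats, mode="exact", tol=1e-8)
        independent = pmem.fit_independent_mem(stats)
        acc = pmem.accuracy_index(probs, pairwise, independent)
        assert acc.r == pytest.approx(1.0, abs=1e-3)
        assert acc.k2 == pytest.approx(0.0, abs=1e-6)

    def test_r_is_zero_for_product_distribution(self):
        rates = np.linspace(0.2, 0.8, 7)
        h = np.arctanh(2 * rates - 1)
        probs = pmem.boltzmann(h, np.zeros((7, 7)))
        stats = pmem.stats_from_distribution(probs)
        pairwise = pmem.fit_pmem(stats, mode="exact", tol=1e-8)
        independent = pmem.fit_independent_mem(stats)
        acc = pmem.accuracy_index(probs, pairwise, independent)
        assert abs(acc.r) < 1e-3

    def test_toy_two_channel_hand_computation(self):
        # Pe over states (--, -+, +-, ++) with symmetric marginals
        pe = np.array([0.4, 0.1, 0.1, 0.4])
        # independent baseline: both activations are 0 -> uniform(1/4);
        # K1 written out by hand:
        k1_hand = (
            2 * 0.4 * np.log2(0.4 / 0.25) + 2 * 0.1 * np.log2(0.1 / 0.25)
        )
        # at C=2 the pairwise model matches any exchangeable Pe exactly
        stats = pmem.stats_from_distribution(pe)
        pairwise = pmem.fit_pmem(stats, mode="exact", tol=1e-9)
        independent = pmem.fit_independent_mem(stats)
        acc = pmem.accuracy_index(pe, pairwise, independent)
        assert acc.k1 == pytest.approx(k1_hand, abs=1e-9)
        assert acc.k2 == pytest.approx(0.0, abs=1e-6)
        assert acc.r == pytest.approx(1.0, abs=1e-4)
        assert pairwise.J[0, 1] == pytest.approx(np.arctanh(0.6), abs=1e-4)

    def test_k1_zero_warns_and_returns_zero(self):
        probs = pmem.boltzmann(np.zeros(3), np.zeros((3, 3)))
        stats = pmem.stats_from_distribution(probs)
        model = pmem.fit_independent_mem(stats)
        with pytest.warns(RuntimeWarning, match="K1 = 0"):
            acc = pmem.accuracy_index(probs, model, model)
        assert acc.r == 0.0

    def test_r_invariant_to_channel_relabeling(self, rng, random_model):
        h, J = random_model
        series = sample_pmem_states(h, J, 2000, seed=3)
        perm = rng.permutation(7)

        def r_of(spins):
            stats = pmem.empirical_stats(pmem.BinaryStateSeries(spins))
            pairwise = pmem.fit_pmem(stats, mode="exact", tol=1e-7)
            independent = pmem.fit_independent_mem(stats)
            return pmem.accuracy_index(stats.probs, pairwise, independent).r

        assert r_of(series.spins) == pytest.approx(
            r_of(series.spins[:, perm]), abs=1e-4
        )
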