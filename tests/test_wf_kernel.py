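import itertools

import numpy as np
import pytest
from scipy.stats import betabinom

from wfkat import (DirichletParams, GenotypeMatrix, build_wf_kernel,
                   column_l2_normalize, estimate_dm_params, recode,
                   symmetrize, wf_closed_form_eigenvalue, wf_kernel,
                   wf_transition)
from wfkat.wf_kernel import (dm_loglik, fit_dm_counts, full_transition_matrix,
                             has_positive_spectrum, simulate_wf_chain)


def _dm_counts(alpha, N, n, seed=0):
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(alpha, size=n)
    return np.array([rng.multinomial(N, p) for p in probs])


class TestDirichletMultinomialFit:
    def test_parameter_recovery(self):
        alpha = np.array([2.0, 5.0, 1.0])
        counts = _dm_counts(alpha, N=4, n=5000, seed=1)
        ahat, boundary = fit_dm_counts(counts, N=4)
        assert not boundary
        assert (np.abs(ahat - alpha) / alpha < 0.15).all()

    def test_exchangeable_columns_give_equal_components(self):
        # replicated columns are strongly over-dispersed, so the MLE is
        # interior, and symmetry forces equal components
        rng = np.random.default_rng(2)
        values = rng.integers(0, 3, size=(400, 1))
        g = GenotypeMatrix(np.repeat(values, 3, axis=1), coding="major")
        dm = estimate_dm_params(g)
        assert not dm.boundary
        assert np.allclose(dm.alpha, dm.alpha[0], rtol=1e-4)

    def test_mle_beats_grid_perturbations(self):
        alpha = np.array([2.0, 5.0, 1.0])
        counts = _dm_counts(alpha, N=4, n=2000, seed=3)
        ahat, _ = fit_dm_counts(counts, N=4)
        ll_hat = dm_loglik(ahat, counts, 4)
        for j in range(3):
            for fac in (0.9, 1.1):
                perturbed = ahat.copy()
                perturbed[j] *= fac
                assert dm_loglik(perturbed, counts, 4) <= ll_hat + 1e-6

    def test_underdispersed_counts_hit_boundary(self):
        # HWE independent loci are under-dispersed vs multinomial: the MLE
        # runs to the concentration ceiling and is flagged
        rng = np.random.default_rng(4)
        g = GenotypeMatrix(rng.binomial(2, 0.4, size=(300, 5)), coding="minor")
        with pytest.warns(UserWarning, match="multinomial limit"):
            dm = estimate_dm_params(g)
        assert dm.boundary
        assert dm.alpha_total == pytest.approx(100 * 10, rel=1e-6)


class TestTransition:
    dm2 = DirichletParams(np.array([1.5, 0.5]), 1.0)

    def test_sampling_probabilities_normalize(self):
        from wfkat.wf_kernel import _log_pi
        for x in itertools.product(range(3), repeat=2):
            pi = np.exp(_log_pi(np.array(x), self.dm2, 4))
            assert pi.sum() == pytest.approx(1.0)

    def test_exhaustive_enumeration_sums_to_one(self):
        # all compositions of N = 4 over the two loci (slack implicit)
        for x_from in itertools.product(range(3), repeat=2):
            total = sum(
                wf_transition(np.array(x_from), np.array(x_to), self.dm2)
                for x_to in itertools.product(range(5), repeat=2)
                if sum(x_to) <= 4
            )
            assert total == pytest.approx(1.0)

    def test_hand_computed_single_locus(self):
        dm = DirichletParams(np.array([1.0]), 1.0)
        # pi = ((2+1)/4, (0+1)/4) = (3/4, 1/4); P(x_to=2) = (3/4)^2
        prob = wf_transition(np.array([2]), np.array([2]), dm)
        assert prob == pytest.approx(0.5625)

    def test_invalid_entries_rejected(self):
        dm1 = DirichletParams(np.array([1.0]), 1.0)
        with pytest.raises(ValueError):
            wf_transition(np.array([3]), np.array([0]), dm1)
        with pytest.raises(ValueError):
            wf_transition(np.array([1]), np.array([-1]), dm1)

    def test_overfull_target_has_zero_probability(self):
        dm = DirichletParams(np.array([1.0, 1.0]), 1.0)
        assert wf_transition(np.array([1, 1]), np.array([4, 4]), dm) == 0.0


class TestClosedFormEigenvalues:
    @pytest.mark.parametrize("i,p,expected", [
        (0, 2, 1.0), (1, 2, 1.0), (2, 2, 0.75), (0, 5, 1.0), (1, 5, 1.0),
    ])
    def test_printed_values(self, i, p, expected):
        assert wf_closed_form_eigenvalue(i, p) == pytest.approx(expected)

    def test_positive_and_nonincreasing(self):
        vals = [wf_closed_form_eigenvalue(i, 3) for i in range(6)]
        assert all(v > 0 for v in vals)
        assert all(vals[i] >= vals[i + 1] for i in range(1, 5))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            wf_closed_form_eigenvalue(4, 2)

    def test_matches_full_chain_spectrum_at_small_alpha(self):
        # the chain's spectrum is the closed form damped by the mutation
        # mass; with alpha -> 0 the two coincide (incl. multiplicities)
        for p in (1, 2):
            dm = DirichletParams(np.full(p, 1e-5), 1e-5)
            T, _ = full_transition_matrix(dm, p)
            assert np.allclose(T.sum(axis=1), 1.0)
            ev = np.linalg.eigvals(T)
            assert np.abs(ev.imag).max() < 1e-8
            assert ev.real.min() > 0
            top = np.sort(ev.real)[::-1]
            closed = sorted(
                (wf_closed_form_eigenvalue(i, p)
                 for i in range(2 * p) for _ in range(_multiplicity(i, p))),
                reverse=True)
            assert np.allclose(top[: len(closed)], closed, atol=1e-3)


def _multiplicity(i, p):
    """Number of degree-i monomials in p variables (eigenvalue multiplicity
    of the resampling chain over the p+1-category composition space)."""
    from math import comb
    return comb(i + p - 1, i)


class TestKernelConstruction:
    @pytest.fixture
    def small(self):
        rng = np.random.default_rng(7)
        g = GenotypeMatrix(rng.integers(0, 3, size=(3, 2)), coding="minor")
        dm = DirichletParams(np.array([1.2, 0.8]), 1.5)
        return g, dm

    def test_entries_match_pairwise_transitions(self, small):
        g, dm = small
        K = build_wf_kernel(g, dm)
        major = recode(g, "major").values
        direct = np.array([[wf_transition(major[j], major[i], dm)
                            for j in range(3)] for i in range(3)])
        # construction rescales by a common positive factor only
        ratio = K.values / direct
        assert np.allclose(ratio, ratio[0, 0])

    def test_entries_bounded_and_positive(self, tg_like_panel):
        with pytest.warns(UserWarning):
            dm = estimate_dm_params(tg_like_panel)
        K = build_wf_kernel(tg_like_panel, dm)
        assert (K.values > 0).all() and (K.values <= 1.0).all()
        assert np.isfinite(K.values).all()

    def test_duplicate_individuals_have_identical_columns(self, small):
        g, dm = small
        values = np.vstack([g.values, g.values[0]])
        g2 = GenotypeMatrix(values, coding="minor")
        K = build_wf_kernel(g2, dm)
        assert np.allclose(K.values[:, 0], K.values[:, 3])
        assert np.allclose(K.values[0, :], K.values[3, :])


class TestScalingAndSymmetrization:
    def test_identity_preserved(self):
        K = column_l2_normalize(np.eye(4))
        assert np.allclose(K.values, np.eye(4))

    def test_unit_column_norms(self):
        rng = np.random.default_rng(1)
        K = column_l2_normalize(rng.uniform(0.1, 1.0, (5, 5)))
        assert np.allclose(np.linalg.norm(K.values, axis=0), 1.0)

    def test_matches_hand_division(self):
        rng = np.random.default_rng(2)
        M = rng.uniform(0.1, 1.0, (3, 3))
        expected = np.column_stack([M[:, j] / np.linalg.norm(M[:, j])
                                    for j in range(3)])
        assert np.allclose(column_l2_normalize(M).values, expected)

    def test_zero_column_rejected(self):
        M = np.eye(3)
        M[:, 1] = 0.0
        with pytest.raises(ValueError, match="zero column"):
            column_l2_normalize(M)

    def test_symmetric_input_is_additive_fixed_point(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        assert np.allclose(symmetrize(S, "additive").values, S)

    def test_two_by_two_arithmetic(self):
        M = np.array([[1.0, 0.2], [0.4, 1.0]])
        assert np.allclose(symmetrize(M, "additive").values,
                           [[1.0, 0.3], [0.3, 1.0]])
        assert np.allclose(symmetrize(M, "multiplicative").values,
                           [[1.0, 0.08], [0.08, 1.0]])

    def test_multiplicative_wf_kernels_are_psd_across_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = GenotypeMatrix(rng.integers(0, 3, size=(30, 4)))
            dm = DirichletParams(rng.uniform(0.5, 3.0, 4),
                                 rng.uniform(0.5, 3.0))
            K = symmetrize(column_l2_normalize(build_wf_kernel(g, dm)),
                           "multiplicative")
            ev = np.linalg.eigvalsh(K.values)
            assert ev.min() >= -1e-10 * max(ev.max(), 1.0)

    def test_additive_symmetrization_can_lose_psd_on_sampled_chains(self):
        # positivity of the asymmetric spectrum does NOT carry over to the
        # symmetric part for transition matrices restricted to a finite
        # sample of individuals: this documented counterexample is why the
        # multiplicative symmetrization is the default
        rng = np.random.default_rng(100)
        g = GenotypeMatrix(rng.integers(0, 3, size=(25, 3)))
        dm = DirichletParams(rng.uniform(0.5, 2.0, 3), 1.0)
        K = column_l2_normalize(build_wf_kernel(g, dm)).values
        assert has_positive_spectrum(K, tol=1e-8)
        ev_add = np.linalg.eigvalsh(0.5 * (K + K.T))
        assert ev_add.min() < -1e-6 * ev_add.max()
        ev_mult = np.linalg.eigvalsh(K * K.T)
        assert ev_mult.min() >= -1e-10 * ev_mult.max()


class TestMercerFacts:
    """Symmetrization devices preserve spectrum positivity."""

    @staticmethod
    def _positive_spectrum_matrix(rng, n=8):
        # product of two SPD matrices: real positive eigenvalues, asymmetric
        A = rng.standard_normal((n, n))
        B = rng.standard_normal((n, n))
        return (A @ A.T + n * np.eye(n)) @ (B @ B.T + n * np.eye(n)) / n ** 2

    def test_facts_on_random_positive_spectrum_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            K = self._positive_spectrum_matrix(rng)
            Q = self._positive_spectrum_matrix(rng)
            assert has_positive_spectrum(K)
            assert has_positive_spectrum(0.5 * (K + K.T))     # Fact 1
            assert has_positive_spectrum(K @ K.T)             # Fact 2
            assert has_positive_spectrum(K * K.T)             # Fact 3
            assert has_positive_spectrum(K @ Q)               # Fact 4

    def test_facts_on_column_scaled_wf_kernels(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            g = GenotypeMatrix(rng.integers(0, 3, size=(25, 3)))
            dm = DirichletParams(rng.uniform(0.5, 2.0, 3), 1.0)
            K = column_l2_normalize(build_wf_kernel(g, dm)).values
            assert has_positive_spectrum(K, tol=1e-8)
            assert has_positive_spectrum(K @ K.T, tol=1e-8)
            assert has_positive_spectrum(K * K.T, tol=1e-8)


class TestStationarity:
    def test_single_locus_chain_approaches_dirichlet_multinomial(self):
        # the DM is the approximate stationary law; the approximation is
        # good in the moderate-to-high concentration regime (at p = 1 the
        # exact stationary law sits within TV 0.04 of the DM for |alpha|
        # = 10, but ~0.1 away at |alpha| = 2)
        dm = DirichletParams(np.array([5.0]), 5.0)
        states = simulate_wf_chain(dm, p=1, steps=100_000, seed=5)[:, 0]
        emp = np.bincount(states, minlength=3) / len(states)
        target = betabinom.pmf(np.arange(3), 2, dm.alpha[0], dm.alpha_slack)
        tv = 0.5 * np.abs(emp - target).sum()
        assert tv < 0.05

    def test_dm_approximation_improves_with_concentration(self):
        def exact_tv(a):
            dm = DirichletParams(np.array([a]), a)
            T, states = full_transition_matrix(dm, 1)
            w, V = np.linalg.eig(T.T)
            pi = np.abs(V[:, np.argmin(np.abs(w - 1))].real)
            pi /= pi.sum()
            target = betabinom.pmf(np.arange(3), 2, a, a)
            return 0.5 * np.abs(pi - target).sum()

        tvs = [exact_tv(a) for a in (0.5, 2.0, 5.0, 20.0)]
        assert all(tvs[i] > tvs[i + 1] for i in range(3))
        assert tvs[-1] < 0.05


class TestPipeline:
    def test_wf_kernel_flags(self, tg_like_panel):
        with pytest.warns(UserWarning):
            K = wf_kernel(tg_like_panel)
        assert K.symmetric and K.psd_checked
        assert K.meta["symmetrization"] == "multiplicative"

    def test_kernel_tsv_roundtrip(self, tmp_path, toy_genotypes):
        dm = DirichletParams(np.array([1.0, 1.0]), 1.0)
        K = wf_kernel(toy_genotypes, dm=dm, symmetrization="additive")
        out = tmp_path / "K.tsv"
        K.to_tsv(out)
        back = K.from_tsv(out)
        assert np.allclose(back.values, K.values)
        assert back.symmetric
        assert back.meta["symmetrization"] == "additive"
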