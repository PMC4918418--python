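"""Site averaging, exchangeabilities, and the (Omega, omega) statistics."""

import numpy as np
import pytest

from mutselhet.genetic_code import AA_INDEX
from mutselhet.heterogeneity import (
    average_model,
    effective_n_amino_acids,
    exchangeability_from_profiles,
    mixture_statistics,
    normalize_exchangeability,
    normalize_rate_matrix,
    relative_rate,
    relative_rates,
)
from mutselhet.mutsel import f81_approximation, rate_from_frequencies

from conftest import random_profiles


def brute_force_flux_average(P, mutation):
    """<pi_L,X Q_L,XY>_L / <pi_L,X>_L with the per-site F81-style process."""
    num = np.zeros((20, 20))
    for pi in P:
        Q = f81_approximation(pi, mutation).Q
        np.fill_diagonal(Q, 0.0)
        num += pi[:, None] * Q
    num /= len(P)
    return num / P.mean(axis=0)[:, None]


class TestAverageModel:
    def test_identical_profiles_have_zero_covariance(self, mutation, rng):
        pi = rng.dirichlet(np.full(20, 1.0))
        am = average_model([pi, pi, pi], mutation)
        assert np.max(np.abs(am.cov)) < 1e-18
        off = ~np.eye(20, dtype=bool)
        expected = mutation.vS * pi[None, :]
        np.testing.assert_allclose(am.Qhat[off], expected[off], atol=1e-14)

    def test_covariance_form_equals_flux_average(self, mutation, rng):
        for _ in range(30):
            P = random_profiles(rng, rng.integers(5, 40))
            am = average_model(P, mutation)
            brute = brute_force_flux_average(P, mutation)
            off = ~np.eye(20, dtype=bool)
            assert np.max(np.abs(am.Qhat - brute)[off]) < 1e-10

    def test_cov_rows_sum_to_zero(self, mutation, rng):
        P = random_profiles(rng, 50)
        am = average_model(P, mutation)
        assert np.max(np.abs(am.cov.sum(axis=1))) < 1e-10
        np.testing.assert_array_equal(am.S, am.S.T)

    def test_two_disjoint_sites_anticorrelate(self, mutation):
        eps = 1e-3
        site1 = np.full(20, eps / 19)
        site1[AA_INDEX["I"]] = 1.0 - eps
        site2 = np.full(20, eps / 19)
        site2[AA_INDEX["V"]] = 1.0 - eps
        am = average_model([site1, site2], mutation)
        assert am.cov[AA_INDEX["I"], AA_INDEX["V"]] < 0

    def test_single_profile_rejected(self, mutation):
        with pytest.raises(ValueError):
            average_model([np.full(20, 0.05)], mutation)


class TestExchangeability:
    def test_identical_profiles_give_flat_matrix(self, rng):
        pi = rng.dirichlet(np.full(20, 2.0))
        S = exchangeability_from_profiles([pi, pi], normalize=False)
        off = ~np.eye(20, dtype=bool)
        np.testing.assert_allclose(S[off], 1.0, atol=1e-10)

    def test_block_classes_order_pairs(self, rng):
        """Sites alternating between an {I,V} class and a {D,E} class make
        within-class exchangeabilities exceed the cross-class ones."""
        P = []
        for k in range(200):
            p = np.full(20, 1e-4)
            a, b = ("I", "V") if k % 2 == 0 else ("D", "E")
            split = rng.uniform(0.3, 0.7)
            p[AA_INDEX[a]] = split
            p[AA_INDEX[b]] = 1.0 - split
            P.append(p / p.sum())
        S = exchangeability_from_profiles(P)
        i, v, d = AA_INDEX["I"], AA_INDEX["V"], AA_INDEX["D"]
        e = AA_INDEX["E"]
        assert S[i, v] > S[i, d] and S[d, e] > S[i, d]

    def test_symmetry_is_exact(self, rng):
        P = random_profiles(rng, 37)
        S = exchangeability_from_profiles(P)
        np.testing.assert_array_equal(S, S.T)

    def test_normalisation_sets_unit_average_rate(self, rng):
        P = random_profiles(rng, 30)
        S = exchangeability_from_profiles(P)
        pihat = P.mean(axis=0)
        off = ~np.eye(20, dtype=bool)
        rate = (np.where(np.isnan(S), 0.0, S) * np.outer(pihat, pihat))[off].sum()
        assert rate == pytest.approx(1.0, abs=1e-12)


class TestOmegaEff:
    def test_uniform_profile_is_twenty(self):
        assert effective_n_amino_acids(np.full(20, 0.05)) == pytest.approx(20.0)

    def test_delta_profile_is_one(self):
        p = np.zeros(20)
        p[7] = 1.0
        assert effective_n_amino_acids(p) == pytest.approx(1.0)

    def test_invariant_to_relabelling(self, rng):
        p = rng.dirichlet(np.full(20, 0.5))
        perm = rng.permutation(20)
        assert effective_n_amino_acids(p[perm]) == pytest.approx(effective_n_amino_acids(p))


class TestRelativeRate:
    def test_neutral_profile_gives_unity(self, mutation):
        assert relative_rate(mutation.lam, mutation) == pytest.approx(1.0, abs=1e-12)

    def test_near_delta_profile_is_strongly_suppressed(self, mutation):
        p = np.full(20, 1e-6 / 19)
        p[AA_INDEX["A"]] = 1.0 - 1e-6
        assert relative_rate(p / p.sum(), mutation) < 1e-3

    def test_invariant_to_mutation_rescaling(self, mutation, rng):
        from mutselhet.genetic_code import MutationModel

        p = random_profiles(rng, 1)[0]
        scaled = MutationModel(v=3.0 * mutation.v, lam=mutation.lam,
                               vS=3.0 * mutation.vS, kappa=mutation.kappa)
        assert relative_rate(p, scaled) == pytest.approx(relative_rate(p, mutation), rel=1e-12)

    def test_batch_matches_scalar(self, mutation, rng):
        P = random_profiles(rng, 7)
        batch = relative_rates(P, mutation)
        singles = [relative_rate(p, mutation) for p in P]
        np.testing.assert_allclose(batch, singles, rtol=1e-12)


class TestMixture:
    def test_single_class_equals_plain_statistics(self, mutation, rng):
        p = random_profiles(rng, 1)[0]
        pt = mixture_statistics([p], [1.0], mutation)
        assert pt.omega_eff == pytest.approx(effective_n_amino_acids(p))
        assert pt.rate_ratio == pytest.approx(relative_rate(p, mutation))

    def test_two_delta_classes_average_to_one(self, mutation):
        p1, p2 = np.zeros(20), np.zeros(20)
        p1[0] = 1.0
        p2[5] = 1.0
        pt = mixture_statistics([p1, p2], [0.5, 0.5], mutation, pseudocount=1e-10)
        assert pt.omega_eff == pytest.approx(1.0, abs=1e-6)

    def test_mixture_omega_below_pooled_omega(self, mutation, rng):
        """Entropy is concave: averaging profiles can only broaden them."""
        P = random_profiles(rng, 8)
        w = np.full(8, 1.0 / 8)
        mixed = mixture_statistics(P, w, mutation)
        pooled = effective_n_amino_acids(P.mean(axis=0))
        assert mixed.omega_eff <= pooled + 1e-12

    def test_weight_mismatch_rejected(self, mutation, rng):
        P = random_profiles(rng, 3)
        with pytest.raises(ValueError):
            mixture_statistics(P, [0.5, 0.5], mutation)


class TestNormalizeRateMatrix:
    def test_normalised_matrix_has_unit_rate_and_is_idempotent(self, mutation, rng):
        p = random_profiles(rng, 1)[0]
        rm = rate_from_frequencies(p, mutation)
        norm = normalize_rate_matrix(rm)
        assert norm.average_rate() == pytest.approx(1.0, abs=1e-12)
        again = normalize_rate_matrix(norm)
        np.testing.assert_allclose(again.Q, norm.Q, rtol=1e-12)

    def test_scale_invariance(self, mutation, rng):
        from mutselhet.mutsel import SiteRateMatrix

        p = random_profiles(rng, 1)[0]
        rm = rate_from_frequencies(p, mutation)
        scaled = SiteRateMatrix(7.0 * rm.Q, rm.stationary)
        np.testing.assert_allclose(
            normalize_rate_matrix(scaled).Q, normalize_rate_matrix(rm).Q, rtol=1e-12
        )
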