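"""Contact energies, folding free energy, fitness, and the Gillespie simulator."""

import numpy as np
import pytest

from mutselhet.genetic_code import AA_INDEX, build_genetic_code
from mutselhet.stability import (
    ContactStructure,
    NotConvergedError,
    StabilityModel,
    Trajectory,
    burn_in,
    contact_energy,
    fitness_from_dG,
    folding_free_energy,
    instantaneous_site_profile,
    load_contact_potential,
    scaled_unfolded_entropy,
    sf_statistics,
    simulate,
)
from mutselhet.synthetic import generate_structure


@pytest.fixture(scope="module")
def potential():
    return load_contact_potential()


@pytest.fixture(scope="module")
def small_model(potential):
    native, decoys = generate_structure(12, contact_density=2.0, n_decoys=5, seed=3)
    return StabilityModel(potential=potential, native=native, decoys=decoys,
                          log_n_unfolded=scaled_unfolded_entropy(12))


class TestContactEnergy:
    def test_empty_contact_set_is_zero(self, potential):
        s = ContactStructure(5, np.zeros((0, 2), dtype=int))
        assert contact_energy("ACDEF", s, potential) == 0.0

    def test_single_contact(self, potential):
        s = ContactStructure(5, [(0, 3)])
        assert contact_energy("ACDEF", s, potential) == pytest.approx(
            potential[AA_INDEX["A"], AA_INDEX["E"]]
        )

    def test_polyalanine_sums_identical_contacts(self, potential, rng):
        pairs = [(i, i + 2) for i in range(10)]
        s = ContactStructure(12, pairs)
        e = contact_energy("A" * 12, s, potential)
        assert e == pytest.approx(10 * potential[AA_INDEX["A"], AA_INDEX["A"]])

    def test_length_mismatch_rejected(self, potential):
        s = ContactStructure(5, [(0, 3)])
        with pytest.raises(ValueError):
            contact_energy("ACD", s, potential)

    def test_contact_invariants_enforced(self):
        with pytest.raises(ValueError):
            ContactStructure(5, [(0, 1)])  # |i-j| < 2
        with pytest.raises(ValueError):
            ContactStructure(5, [(0, 7)])  # out of range
        with pytest.raises(ValueError):
            ContactStructure(5, [(0, 3), (3, 0)])  # duplicate pair


class TestFoldingFreeEnergy:
    def test_degenerate_decoys_closed_form(self, potential):
        """All decoys identical: sigma = 0 and dG = E_nat - mu + kT ln N."""
        native = ContactStructure(6, [(0, 4), (1, 3)])
        decoy = ContactStructure(6, [(0, 2), (2, 5)])
        model = StabilityModel(potential=potential, native=native,
                               decoys=(decoy, decoy, decoy), log_n_unfolded=np.log(50.0))
        seq = "ACDEFG"
        e_nat = contact_energy(seq, native, potential)
        mu = contact_energy(seq, decoy, potential)
        assert folding_free_energy(seq, model) == pytest.approx(
            e_nat - mu + np.log(50.0), rel=1e-12
        )

    def test_spread_decoys_lower_alternative_free_energy(self, potential):
        """A wider decoy energy distribution stabilises the alternatives,
        raising dG by sigma^2 / (2 kT)."""
        native = ContactStructure(6, [(0, 4)])
        d1 = ContactStructure(6, [(0, 2)])
        d2 = ContactStructure(6, [(1, 5)])
        model = StabilityModel(potential=potential, native=native, decoys=(d1, d2),
                               log_n_unfolded=0.0)
        seq = "ACDEFG"
        e = [contact_energy(seq, d, potential) for d in (d1, d2)]
        expected = (contact_energy(seq, native, potential)
                    - np.mean(e) + np.var(e) / 2.0)
        assert folding_free_energy(seq, model) == pytest.approx(expected, rel=1e-12)

    def test_stabilising_native_gives_negative_dG(self, potential):
        # the native fold pairs the two hydrophobic residues; decoys pair
        # hydrophobics with charged residues, so the native is the optimum
        native = ContactStructure(5, [(0, 4)])   # I-I
        decoys = (ContactStructure(5, [(0, 2)]),  # I-D
                  ContactStructure(5, [(1, 3)]))  # K-E
        model = StabilityModel(potential=potential, native=native, decoys=decoys,
                               log_n_unfolded=0.1)
        assert folding_free_energy("IKDEI", model) < 0

    def test_too_few_decoys_rejected(self, potential):
        native = ContactStructure(6, [(0, 4)])
        model = StabilityModel(potential=potential, native=native,
                               decoys=(ContactStructure(6, [(0, 2)]),))
        with pytest.raises(ValueError):
            folding_free_energy("ACDEFG", model)


class TestFitness:
    def test_symmetry_point(self):
        assert fitness_from_dG(0.0) == pytest.approx(0.5)

    def test_ninety_percent_folded(self):
        assert fitness_from_dG(-np.log(9.0)) == pytest.approx(0.9)

    def test_monotone_and_saturating(self):
        dg = np.linspace(-30, 30, 101)
        f = fitness_from_dG(dg)
        assert np.all(np.diff(f) < 0)
        assert fitness_from_dG(1e4) == 0.0 and fitness_from_dG(-1e4) == 1.0


class TestInstantaneousProfile:
    def test_uncontacted_site_is_neutral(self, potential, mutation):
        """A residue with no contacts contributes nothing to any energy, so
        its instantaneous profile is the code background lambda."""
        native = ContactStructure(6, [(0, 4)])
        decoys = (ContactStructure(6, [(1, 4)]), ContactStructure(6, [(2, 4)]))
        model = StabilityModel(potential=potential, native=native, decoys=decoys)
        prof = instantaneous_site_profile("ACDEFG", 5, model, mutation, scaled_Ne=1000.0)
        np.testing.assert_allclose(prof.pi, mutation.lam, atol=1e-12)

    def test_profile_normalised(self, small_model, mutation):
        prof = instantaneous_site_profile("ACDEFGHIKLMN", 4, small_model, mutation, 30.0)
        assert prof.pi.sum() == pytest.approx(1.0)


def _start(code, n, seed):
    rng = np.random.default_rng(seed)
    return tuple(rng.choice(code.codons, size=n))


def fake_trajectory(dG, n_sites=5):
    """A hand-built trajectory carrying only sampled dG values and flat profiles."""
    n = len(dG)
    return Trajectory(
        start_codons=("GCT",) * n_sites,
        event_times=np.array([]), event_sites=np.array([], dtype=int),
        event_from=np.array([], dtype=int), event_to=np.array([], dtype=int),
        sample_times=np.linspace(0, 10, n),
        sample_profiles=np.full((n, n_sites, 20), 0.05),
        sample_dG=np.asarray(dG, dtype=float),
        duration=10.0, rate_integral=0.0,
    )


class TestSimulate:
    def test_same_seed_reproduces_event_list(self, small_model, mutation, code):
        start = _start(code, 12, 5)
        kw = dict(scaled_Ne=30.0, duration=1.0, sample_interval=0.25, seed=9)
        t1 = simulate(start, small_model, mutation, **kw)
        t2 = simulate(start, small_model, mutation, **kw)
        np.testing.assert_array_equal(t1.event_times, t2.event_times)
        np.testing.assert_array_equal(t1.event_sites, t2.event_sites)
        np.testing.assert_array_equal(t1.event_to, t2.event_to)
        np.testing.assert_allclose(t1.sample_profiles, t2.sample_profiles)

    def test_event_times_increase_and_events_are_single_nucleotide(
        self, small_model, mutation, code
    ):
        start = _start(code, 12, 6)
        traj = simulate(start, small_model, mutation, 30.0, duration=2.0, seed=4)
        assert np.all(np.diff(traj.event_times) > 0)
        for _, _, frm, to in traj.iter_events():
            assert sum(a != b for a, b in zip(frm, to)) == 1
            assert to not in code.stop_codons

    def test_neutral_run_matches_mutation_clock(self, small_model, mutation, code):
        """With selection off, the substitution counter is a Poisson process
        whose intensity is the total mutation rate."""
        start = _start(code, 12, 7)
        traj = simulate(start, small_model, mutation, 0.0, duration=8.0, seed=11)
        n = traj.n_substitutions
        assert n > 100
        ratio = n / traj.rate_integral
        assert abs(ratio - 1.0) < 3.0 / np.sqrt(n)
        stats = sf_statistics(traj, mutation)
        np.testing.assert_allclose(stats.sf_rate, 1.0, atol=1e-9)
        np.testing.assert_allclose(stats.sf_omega, 17.0, atol=3.0)

    def test_lethal_landscape_freezes_amino_acids(self, code):
        """When every amino acid change is catastrophically deleterious, only
        synonymous events occur."""
        pot = np.full((20, 20), 50.0)
        a = AA_INDEX["A"]
        pot[a, a] = -50.0
        native = ContactStructure(8, [(i, i + 2) for i in range(6)])
        decoys = (ContactStructure(8, [(0, 3), (1, 4)]),
                  ContactStructure(8, [(2, 5), (3, 6)]))
        # the unfolded entropy is set so the poly-Ala wild type is folded
        # (dG = -50) while every single amino acid change unfolds the protein
        model = StabilityModel(potential=pot, native=native, decoys=decoys,
                               log_n_unfolded=150.0)
        from mutselhet.genetic_code import codon_averaged_k80

        mutation = codon_averaged_k80(2.0)
        start = tuple(["GCT"] * 8)  # poly-alanine
        traj = simulate(start, model, mutation, scaled_Ne=1e6, duration=2.0, seed=3)
        aa_of = code.aa_index_of_codon()
        assert np.all(aa_of[traj.event_from] == aa_of[traj.event_to])

    def test_bad_inputs_rejected(self, small_model, mutation):
        with pytest.raises(ValueError):
            simulate(("TAA",) * 12, small_model, mutation, 1.0, duration=1.0)
        with pytest.raises(ValueError):
            simulate(("GCT",) * 12, small_model, mutation, 1.0)  # no stop condition


class TestBurnIn:
    def test_substitution_criterion_returns_event_time(self, small_model, mutation, code):
        traj = simulate(_start(code, 12, 8), small_model, mutation, 30.0,
                        n_substitutions=130, sample_interval=0.05, seed=5)
        t0 = burn_in(traj, "substitutions", factor=10)
        assert t0 == traj.event_times[12 * 10 - 1]
        with pytest.raises(NotConvergedError):
            burn_in(traj, "substitutions", factor=1000)

    def test_trend_criterion_accepts_white_noise_immediately(self, rng):
        traj = fake_trajectory(rng.normal(0, 1, 200))
        assert burn_in(traj, "trend") == 0.0

    def test_trend_criterion_rejects_steady_drift(self, rng):
        traj = fake_trajectory(np.linspace(50, -50, 200) + rng.normal(0, 0.1, 200))
        with pytest.raises(NotConvergedError):
            burn_in(traj, "trend")


class TestSFStatistics:
    def test_frozen_profiles_make_sf_equal_sft(self, rng, mutation):
        P = rng.dirichlet(np.full(20, 0.5), size=5) + 1e-6
        P /= P.sum(axis=1, keepdims=True)
        traj = fake_trajectory(np.zeros(30))
        traj.sample_profiles = np.broadcast_to(P, (30, 5, 20)).copy()
        stats = sf_statistics(traj, mutation)
        np.testing.assert_allclose(stats.sf_omega.mean(axis=0), stats.sft_omega, rtol=1e-10)
        np.testing.assert_allclose(stats.sf_rate.mean(axis=0), stats.sft_rate, rtol=1e-8)

    def test_averaging_broadens_profiles(self, small_model, mutation, code):
        """Entropy concavity: instantaneous Omega <= Omega of the time-averaged
        profile per site, and site-averaging broadens further."""
        traj = simulate(_start(code, 12, 9), small_model, mutation, 30.0,
                        n_substitutions=400, sample_interval=0.05, seed=6)
        t0 = burn_in(traj, factor=10)
        stats = sf_statistics(traj, mutation, burn_in_time=t0)
        assert np.all(stats.sf_omega.mean(axis=0) <= stats.sft_omega + 1e-9)
        assert stats.sft_omega.mean() <= stats.sfts_omega + 1e-9
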