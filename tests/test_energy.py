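"""Random-binder ensemble and window free-energy kernel."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncbind.energy import (
    EnergyProfile,
    InvalidWindowError,
    ModelParams,
    RandomBinder,
    SequenceWindow,
    binder_free_energies,
    encode_sequence,
    energy_profile,
    kbt_to_kcal_per_mol,
    mean_free_energy,
    sample_binder_ensemble,
    spectrum_width,
    tract_to_iid_width_ratio,
    window_free_energy,
)


class TestModelParams:
    def test_defaults_are_genomic_mode(self, default_params):
        p = default_params
        assert (p.M, p.L, p.sigma, p.n_binders) == (8, 50, 2.0, 250)
        assert p.n_starts == 43
        assert p.pbm().L == 36 and p.pbm().n_starts == 29

    @pytest.mark.parametrize(
        "kwargs", [dict(L=5, M=8), dict(M=0), dict(sigma=-1), dict(n_binders=0), dict(kBT=0)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_energy_scale_conversion(self):
        # 2 kBT at physiological temperature is about 1.2 kcal/mol
        assert kbt_to_kcal_per_mol(2.0, 300.0) == pytest.approx(1.2, abs=0.01)


class TestEnsemble:
    def test_shape_and_reproducibility(self, default_params, default_ensemble):
        assert len(default_ensemble) == 250
        assert default_ensemble.K.shape == (250, 4)
        again = sample_binder_ensemble(default_params)
        np.testing.assert_array_equal(default_ensemble.K, again.K)
        binder = default_ensemble[0]
        assert set(binder.K) == set("ACGT")

    def test_zero_variance_limit(self):
        ens = sample_binder_ensemble(ModelParams(sigma=0.0, n_binders=1))
        np.testing.assert_array_equal(ens.K, np.zeros((1, 4)))

    def test_large_sample_moments(self):
        n = 10**5
        ens = sample_binder_ensemble(ModelParams(n_binders=n, seed=3))
        ka = ens.K[:, 0]
        assert abs(ka.mean()) < 3 * 2.0 / math.sqrt(n)
        assert ka.std() == pytest.approx(2.0, rel=0.01)

    def test_binder_requires_four_finite_constants(self):
        with pytest.raises(ValueError):
            RandomBinder({"A": 1.0, "C": 2.0})
        with pytest.raises(ValueError):
            RandomBinder({"A": np.inf, "C": 0.0, "G": 0.0, "T": 0.0})


class TestSequenceWindow:
    def test_one_hot_encoding(self):
        w = SequenceWindow("ACGTN")
        enc = w.encoding
        assert enc[:4].sum(axis=1).tolist() == [1, 1, 1, 1]
        assert enc[4].sum() == 0  # N row is all zeros
        assert not w.is_valid
        assert SequenceWindow("acgt").is_valid  # lowercase accepted


class TestEnergyProfile:
    def test_homopolymer_energy_is_MK(self):
        K = np.array([1.0, 0.0, 0.0, 0.0])
        prof = energy_profile(K, "AAAAA", M=3)
        np.testing.assert_allclose(prof.U, [-3.0, -3.0, -3.0])

    def test_direct_three_contact_sum(self):
        K = np.array([1.0, 3.0, 4.0, 2.0])  # A, C, G, T
        prof = energy_profile(K, "ACG", M=3)
        np.testing.assert_allclose(prof.U, [-8.0])

    def test_uniform_constants_give_composition_independent_energy(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30))
        prof = energy_profile(np.full(4, 2.5), seq, M=4)
        np.testing.assert_allclose(prof.U, -10.0)

    def test_window_errors(self):
        with pytest.raises(ValueError):
            energy_profile(np.zeros(4), "AC", M=3)
        with pytest.raises(InvalidWindowError):
            energy_profile(np.zeros(4), "ACGTN", M=3)


class TestWindowFreeEnergy:
    def test_single_state(self):
        assert window_free_energy(np.array([-1.0])) == pytest.approx(-1.0)

    def test_two_state_sum(self):
        F = window_free_energy(np.array([0.0, -math.log(3)]))
        assert F == pytest.approx(-math.log(4))

    @pytest.mark.parametrize("u,n", [(0.7, 5), (-3.2, 17), (10.0, 1)])
    def test_equal_energy_closed_form(self, u, n):
        F = window_free_energy(np.full(n, u))
        assert F == pytest.approx(u - math.log(n), abs=1e-12)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            window_free_energy(np.array([]))

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=60),
        st.floats(0.3, 3.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_boltzmann_bound(self, energies, kBT):
        # F <= min U, with equality only for a single state
        U = np.array(energies)
        F = window_free_energy(U, kBT)
        assert F <= U.min() + 1e-9

    def test_logsumexp_matches_naive_enumeration(self, rng):
        # small windows allow a brute-force partition function
        for _ in range(30):
            M = int(rng.integers(1, 5))
            n = int(rng.integers(M, 13))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            K = rng.normal(0, 2, 4)
            lut = dict(zip("ACGT", K))
            naive_U = [
                -sum(lut[seq[j]] for j in range(i, i + M)) for i in range(n - M + 1)
            ]
            naive_F = -math.log(sum(math.exp(-u) for u in naive_U))
            prof = energy_profile(K, seq, M)
            np.testing.assert_allclose(prof.U, naive_U, atol=1e-10)
            assert window_free_energy(prof) == pytest.approx(naive_F, abs=1e-10)


class TestMeanFreeEnergy:
    def test_homopolymer_mean_is_entropy_term(self):
        # <F> -> -ln(n_starts): the Gaussian MK_A term has zero mean
        p = ModelParams(n_binders=10_000, seed=11)
        ens = sample_binder_ensemble(p)
        F, f = mean_free_energy(ens, "A" * 50, p)
        se = p.M * p.sigma / math.sqrt(p.n_binders)
        assert abs(F - (-math.log(43))) < 3 * se
        assert f == pytest.approx(F / 8)

    def test_sigma_zero_is_exact_for_any_sequence(self, rng):
        p = ModelParams(sigma=0.0, n_binders=5, seed=0)
        ens = sample_binder_ensemble(p)
        seq = "".join(rng.choice(list("ACGT"), size=50))
        F, _ = mean_free_energy(ens, seq, p)
        assert F == pytest.approx(-math.log(43), abs=1e-12)

    def test_tracts_lower_free_energy_vs_shuffle(self, rng):
        p = ModelParams(n_binders=2000, seed=5)
        ens = sample_binder_ensemble(p)
        tract = ("A" * 10 + "T" * 10) * 5   # alternating tracts, 50 bp
        shuffled = "".join(rng.permutation(list(tract)))
        F_tract, _ = mean_free_energy(ens, tract, p)
        F_shuf, _ = mean_free_energy(ens, shuffled, p)
        assert F_tract < F_shuf

    def test_standard_error_halves_when_ensemble_quadruples(self, rng):
        # sqrt(n) scaling of the ensemble-mean estimator
        seq = "".join(rng.choice(list("ACGT"), size=50))
        means = {n: [] for n in (100, 400)}
        for n in means:
            for seed in range(40):
                p = ModelParams(n_binders=n, seed=1000 + seed)
                F, _ = mean_free_energy(sample_binder_ensemble(p), seq, p)
                means[n].append(F)
        ratio = np.std(means[100], ddof=1) / np.std(means[400], ddof=1)
        assert 1.4 < ratio < 2.9


class TestSpectrumWidth:
    def test_iid_matches_multinomial_closed_form(self):
        p = ModelParams(n_binders=500)
        sigma_u = spectrum_width("iid-random", p, n_samples=10**5, seed=2)
        assert sigma_u == pytest.approx(math.sqrt(88), rel=0.05)

    def test_tracts_reach_full_footprint_variance(self):
        p = ModelParams(n_binders=500)
        sigma_u = spectrum_width("two-type-tracts", p, n_samples=10**5, seed=2)
        assert sigma_u == pytest.approx(16.0, rel=0.05)

    @pytest.mark.parametrize("M", [8, 50, 200])
    def test_width_ratio_matches_finite_M_form(self, M):
        # the K constants are shared across positions, so the Monte-Carlo
        # error is dominated by the binder axis: use a large ensemble
        p = ModelParams(M=M, L=max(M, 50), n_binders=5000)
        r = spectrum_width("two-type-tracts", p, 10**6, seed=7) / spectrum_width(
            "iid-random", p, 10**6, seed=8
        )
        assert r == pytest.approx(tract_to_iid_width_ratio(M), rel=0.05)

    def test_unknown_sequence_class_rejected(self, default_params):
        with pytest.raises(ValueError):
            spectrum_width("genomic", default_params, 1000)


def test_shared_kernel_consistency(default_params, default_ensemble):
    # vectorized per-binder free energies agree with the scalar path
    seq = "ACGTAC" * 10
    F_vec = binder_free_energies(encode_sequence(seq[:50]), default_ensemble.K, 8)
    F_scalar = [
        window_free_energy(energy_profile(default_ensemble.K[i], seq[:50], 8))
        for i in range(5)
    ]
    np.testing.assert_allclose(F_vec[:5], F_scalar, atol=1e-10)
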