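"""Photocycle propagation, cube synthesis, SVD and kinetic fitting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from kcrkit.photocycle import (IdentifiabilityError, IdentifiabilityWarning,
                               PhotocycleScheme, SpeciesSpectrum,
                               TransientAbsorptionCube,
                               default_hckcr1_scheme, default_species_spectra,
                               fit_target_scheme, global_exponential_fit,
                               propagate_scheme, proton_release_trace,
                               svd_rank, synthesize_cube)
from kcrkit.synthetic import gen_transient_absorption


def _chain(k1, k2):
    return PhotocycleScheme(["A", "B"],
                            {("A", "B"): k1, ("B", "ground"): k2},
                            {"A": 1.0})


class TestPropagateScheme:
    def test_single_species_decay(self):
        s = PhotocycleScheme(["A"], {("A", "ground"): 3.0}, {"A": 1.0})
        t = np.linspace(0, 2, 50)
        C = propagate_scheme(s, t)
        assert np.allclose(C[0], np.exp(-3.0 * t), atol=1e-12)

    def test_two_step_chain_matches_bateman_closed_form(self):
        t = np.linspace(0, 5, 80)
        C = propagate_scheme(_chain(2.0, 1.0), t)
        assert np.allclose(C[1], 2.0 * (np.exp(-t) - np.exp(-2 * t)), atol=1e-12)

    def test_total_population_conserved(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 6))
            names = [f"S{i}" for i in range(n)]
            rates = {}
            for i, a in enumerate(names):
                targets = names[i + 1:] + ["ground"]
                for b in rng.choice(targets, size=min(2, len(targets)),
                                    replace=False):
                    rates[(a, str(b))] = float(rng.uniform(0.1, 50.0))
            init = {names[0]: 0.7, names[1]: 0.2}
            s = PhotocycleScheme(names, rates, init)
            C = propagate_scheme(s, np.linspace(0, 3, 40))
            assert np.abs(C.sum(axis=0) - 1.0).max() < 1e-9

    def test_matches_stiff_ode_oracle(self, rng):
        # eigendecomposition path vs an independent LSODA integration
        for _ in range(10):
            k = rng.uniform(0.5, 200.0, size=3)
            s = PhotocycleScheme(
                ["A", "B", "C"],
                {("A", "B"): k[0], ("B", "C"): k[1], ("C", "ground"): k[2]},
                {"A": 1.0})
            t = np.linspace(0, 1, 30)
            C = propagate_scheme(s, t)
            sol = solve_ivp(lambda _, c: s.generator() @ c, (0, 1),
                            s.initial_vector(), t_eval=t, method="LSODA",
                            rtol=1e-11, atol=1e-13)
            assert np.abs(C - sol.y).max() < 1e-6

    def test_degenerate_rates_fall_back_to_ode(self):
        # coincident eigenvalues make the eigenbasis defective
        s = _chain(1.0, 1.0)
        t = np.linspace(0, 4, 60)
        with pytest.warns(UserWarning, match="defective"):
            C = propagate_scheme(s, t)
        assert np.allclose(C[1], t * np.exp(-t), atol=1e-7)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            propagate_scheme(_chain(1.0, 2.0), np.array([-1.0, 0.0]))


class TestSynthesizeCube:
    def _spectra(self, wl):
        return {"A": SpeciesSpectrum(wl, np.exp(-((wl - 500) / 30) ** 2)),
                "B": SpeciesSpectrum(wl, np.exp(-((wl - 400) / 30) ** 2))}

    def test_zero_populations_give_zero_cube(self):
        wl = np.arange(350.0, 650.0, 5.0)
        s = _chain(1.0, 2.0)
        t = np.array([0.0, 1.0])
        cube = synthesize_cube(s, np.zeros((3, 2)), t, self._spectra(wl))
        assert not cube.delta_A.any()

    def test_unit_population_replicates_spectrum(self):
        wl = np.arange(350.0, 650.0, 5.0)
        spectra = self._spectra(wl)
        s = _chain(1.0, 2.0)
        pops = np.zeros((3, 4))
        pops[0] = 1.0
        cube = synthesize_cube(s, pops, np.arange(4.0), spectra)
        assert np.allclose(cube.delta_A,
                           spectra["A"].delta_epsilon[:, None] * np.ones(4))

    def test_linear_in_populations(self):
        wl = np.arange(350.0, 650.0, 5.0)
        spectra = self._spectra(wl)
        s = _chain(1.0, 2.0)
        pops = np.zeros((3, 1))
        pops[0, 0] = pops[1, 0] = 0.5
        cube = synthesize_cube(s, pops, np.array([0.0]), spectra)
        mean = 0.5 * (spectra["A"].delta_epsilon + spectra["B"].delta_epsilon)
        assert np.allclose(cube.delta_A[:, 0], mean)

    def test_grid_mismatch_rejected(self):
        wl = np.arange(350.0, 650.0, 5.0)
        bad = {"A": SpeciesSpectrum(wl, np.ones_like(wl)),
               "B": SpeciesSpectrum(wl[:-1], np.ones(wl.size - 1))}
        with pytest.raises(ValueError, match="mismatched"):
            synthesize_cube(_chain(1.0, 2.0), np.zeros((3, 1)),
                            np.array([0.0]), bad)


def _distinct_cube(n_species, noise_sd=0.0, rng=None):
    """Cube with n spectrally and kinetically distinct species."""
    wl = np.arange(350.0, 701.0, 2.0)
    t = np.logspace(-4, 1, 120)
    centers = np.linspace(400, 650, n_species)
    rates = np.logspace(0, n_species - 1, n_species)
    dA = np.zeros((wl.size, t.size))
    for c, k in zip(centers, rates):
        dA += np.outer(np.exp(-((wl - c) / 25.0) ** 2), np.exp(-k * t))
    if noise_sd:
        dA = dA + rng.normal(0, noise_sd, dA.shape)
    return TransientAbsorptionCube(wl, t, dA)


class TestSvdRank:
    def test_rank_one_cube(self):
        assert svd_rank(_distinct_cube(1))[0] == 1

    def test_four_distinct_species_noiseless(self):
        assert svd_rank(_distinct_cube(4))[0] == 4

    def test_four_species_at_snr_100(self, rng):
        cube = _distinct_cube(4)
        peak = np.abs(cube.delta_A).max()
        cube.delta_A += rng.normal(0, peak / 100, cube.delta_A.shape)
        assert svd_rank(cube)[0] == 4

    def test_significant_components_explain_99pct_variance(self):
        cube = _distinct_cube(4)
        rank, s, U, Vt = svd_rank(cube)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        explained = 1 - np.sum((cube.delta_A - recon) ** 2) / np.sum(cube.delta_A ** 2)
        assert explained >= 0.99

    def test_non_finite_cube_rejected(self):
        cube = _distinct_cube(2)
        cube.delta_A[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            svd_rank(cube)


class TestGlobalExponentialFit:
    def test_single_component_recovered_exactly(self):
        cube = _distinct_cube(1)
        res = global_exponential_fit(cube, 1)
        assert res.taus_s[0] == pytest.approx(1.0, rel=1e-6)
        assert res.residual_norm < 1e-8

    def test_chain_taus_match_rate_matrix_eigenvalues(self):
        # relaxation eigenvalues of a unidirectional chain are its rates
        rates = [200.0, 20.0, 2.0]
        s = PhotocycleScheme(
            ["A", "B", "C"],
            {("A", "B"): rates[0], ("B", "C"): rates[1],
             ("C", "ground"): rates[2]}, {"A": 1.0})
        wl = np.arange(350.0, 701.0, 2.0)
        spectra = {n: SpeciesSpectrum(wl, np.exp(-((wl - c) / 25.0) ** 2))
                   for n, c in zip("ABC", (420.0, 520.0, 620.0))}
        t = np.logspace(-4, 1, 200)
        cube = synthesize_cube(s, propagate_scheme(s, t), t, spectra)
        res = global_exponential_fit(cube, 3)
        assert np.allclose(np.sort(1.0 / res.taus_s), np.sort(rates), rtol=0.10)

    def test_residual_at_noise_floor_snr50(self):
        cube, truth = gen_transient_absorption(
            snr=50, seed=11, times_s=np.logspace(-6, 1, 200))
        res = global_exponential_fit(cube, 8, seed=11)
        noise_norm = truth.params["noise_sd"] * np.sqrt(cube.delta_A.size)
        assert res.residual_norm <= 1.1 * noise_norm


class TestFitTargetScheme:
    def test_two_state_chain_noiseless_rates_exact(self):
        wl = np.arange(350.0, 701.0, 2.0)
        spectra = {"A": SpeciesSpectrum(wl, np.exp(-((wl - 430) / 25.0) ** 2)),
                   "B": SpeciesSpectrum(wl, np.exp(-((wl - 580) / 25.0) ** 2))}
        truth_scheme = _chain(50.0, 5.0)
        t = np.logspace(-4, 1, 150)
        cube = synthesize_cube(truth_scheme, propagate_scheme(truth_scheme, t),
                               t, spectra)
        topo = PhotocycleScheme(["A", "B"],
                                {("A", "B"): None, ("B", "ground"): None},
                                {"A": 1.0})
        res = fit_target_scheme(cube, topo,
                                initial_rates={("A", "B"): 30.0,
                                               ("B", "ground"): 8.0})
        assert res.rates[("A", "B")] == pytest.approx(50.0, rel=1e-3)
        assert res.rates[("B", "ground")] == pytest.approx(5.0, rel=1e-3)

    def test_overparameterized_topology_rejected(self):
        cube = _distinct_cube(2)
        topo = PhotocycleScheme(
            ["A", "B"],
            {("A", "B"): None, ("B", "ground"): None, ("A", "ground"): None},
            {"A": 1.0})
        with pytest.raises(IdentifiabilityError, match="free rates"):
            fit_target_scheme(cube, topo)

    def test_degenerate_equal_rates_warn(self):
        # k1 = k2 sits on the exchange-degenerate manifold of a chain
        wl = np.arange(350.0, 701.0, 2.0)
        spectra = {"A": SpeciesSpectrum(wl, np.exp(-((wl - 430) / 25.0) ** 2)),
                   "B": SpeciesSpectrum(wl, np.exp(-((wl - 580) / 25.0) ** 2))}
        with pytest.warns(UserWarning):
            truth_scheme = _chain(10.0, 10.0)
            t = np.logspace(-4, 1, 120)
            cube = synthesize_cube(truth_scheme,
                                   propagate_scheme(truth_scheme, t), t, spectra)
            topo = PhotocycleScheme(["A", "B"],
                                    {("A", "B"): None, ("B", "ground"): None},
                                    {"A": 1.0})
            res = fit_target_scheme(cube, topo,
                                    initial_rates={("A", "B"): 10.0,
                                                   ("B", "ground"): 10.0})
        assert res.warnings


class TestProtonRelease:
    def test_identical_traces_cancel(self):
        t = np.linspace(0, 1e-2, 200)
        y = np.exp(-t / 1e-3)
        res = proton_release_trace(t, y, t, y)
        assert np.allclose(res.difference, 0.0)

    def test_release_delayed_one_ms_after_reference_rise(self):
        t = np.linspace(0, 10e-3, 2001)  # 5 us sampling
        ref = 1.0 - np.exp(-t / 0.5e-3)              # M-rise, half at ~0.35 ms
        release = 1.0 - np.exp(-(t - 1e-3).clip(0) / 0.5e-3)  # shifted 1 ms
        res = proton_release_trace(t, release, t, np.zeros_like(t),
                                   reference_trace=ref)
        assert res.lag_s == pytest.approx(1e-3, abs=1e-5)

    def test_amplitude_scaled_difference_is_proportional(self):
        t = np.linspace(0, 1e-2, 200)
        y = 1.0 - np.exp(-t / 1e-3)
        res = proton_release_trace(t, 3.0 * y, t, 1.0 * y)
        assert np.allclose(res.difference, 2.0 * y)

    def test_flat_reference_rejected(self):
        t = np.linspace(0, 1e-2, 200)
        y = 1.0 - np.exp(-t / 1e-3)
        with pytest.raises(ValueError, match="half-rise"):
            proton_release_trace(t, y, t, np.zeros_like(t),
                                 reference_trace=np.ones_like(t))


class TestDefaultScheme:
    def test_relaxation_rates_are_the_chain_rates(self):
        s = default_hckcr1_scheme()
        expected = sorted([2e5, 2e4, 2e3, 2e2, 6e4, 6e3, 6e2, 6e1])
        assert np.allclose(np.sort(s.relaxation_rates()), expected)

    def test_eigenvalues_separated_at_least_3x(self):
        r = np.sort(default_hckcr1_scheme().relaxation_rates())
        assert np.all(r[1:] / r[:-1] >= 3.0)

    def test_species_spectra_share_one_grid(self):
        spectra = default_species_spectra()
        wl = next(iter(spectra.values())).wavelengths_nm
        assert all(np.array_equal(sp.wavelengths_nm, wl)
                   for sp in spectra.values())
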