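"""GHK algebra, I-V reversal estimation, filtering, kinetics and dF/F."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from kcrkit.iontransport import (DffResult, GHKDomainError, IVRecording,
                                 PermeabilitySet, SolutionPair,
                                 compute_dff_metrics, estimate_erev,
                                 extract_photocurrent_metrics,
                                 fit_exponential_kinetics,
                                 ghk_reversal_voltage,
                                 infer_permeability_ratio, lowpass_gaussian)
from kcrkit.synthetic import gen_iv_dataset, gen_photocurrent

RT_F_298_mV = 8.314 * 298.0 / 96485.0 * 1e3  # 25.69 mV


class TestSolutionPair:
    def test_rejects_unknown_ion(self):
        with pytest.raises(ValueError, match="unknown ion"):
            SolutionPair({"K": 4, "Xx": 1}, {"K": 140})

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            SolutionPair({"K": -1}, {"K": 140})

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            SolutionPair({"K": 4}, {"K": 140}, temperature=0.0)


class TestGHKReversal:
    def test_symmetric_solutions_give_zero(self):
        sol = SolutionPair({"K": 140, "Na": 10, "Cl": 150},
                           {"K": 140, "Na": 10, "Cl": 150})
        perms = PermeabilitySet(1.0, 0.3, 0.1)
        assert ghk_reversal_voltage(perms, sol) == pytest.approx(0.0, abs=1e-12)

    def test_nernst_limit(self):
        # p_Na = p_Cl = 0 must reproduce (RT/F) ln([K]o/[K]i) exactly
        sol = SolutionPair({"K": 4}, {"K": 140})
        expected = RT_F_298_mV * math.log(4.0 / 140.0)
        assert ghk_reversal_voltage(PermeabilitySet(), sol) == pytest.approx(
            expected, rel=1e-14)
        assert expected == pytest.approx(-91.3, abs=0.05)

    def test_wild_type_selectivity_reproduces_measured_reversal(
            self, physiological_solutions, k_selective_perms):
        # P_K/P_Na = 25.7 under physiological gradients -> E_rev ~ -68.4 mV
        v = ghk_reversal_voltage(k_selective_perms, physiological_solutions)
        assert v == pytest.approx(-68.4, abs=1.0)

    def test_all_zero_cation_permeability_rejected(self):
        sol = SolutionPair({"K": 4, "Na": 150, "Cl": 154},
                           {"K": 140, "Na": 0, "Cl": 10})
        with pytest.raises(GHKDomainError, match="cation permeability"):
            ghk_reversal_voltage(PermeabilitySet(0.0, 0.0, 1.0, reference="Cl"),
                                 sol)

    def test_zero_denominator_rejected(self):
        sol = SolutionPair({"K": 4}, {"K": 0})
        with pytest.raises(GHKDomainError, match="denominator"):
            ghk_reversal_voltage(PermeabilitySet(), sol)

    def test_monotone_in_outer_and_inner_K(self, k_selective_perms):
        ko_grid = np.linspace(1, 50, 20)
        v_out = [ghk_reversal_voltage(
            k_selective_perms,
            SolutionPair({"K": ko, "Na": 150}, {"K": 140, "Na": 0}))
            for ko in ko_grid]
        assert np.all(np.diff(v_out) > 0)
        v_in = [ghk_reversal_voltage(
            k_selective_perms,
            SolutionPair({"K": 4, "Na": 150}, {"K": ki, "Na": 0}))
            for ki in np.linspace(50, 200, 20)]
        assert np.all(np.diff(v_in) < 0)


class TestPermeabilityInversion:
    def test_symmetric_zero_reversal_gives_unity(self):
        sol = SolutionPair({"K": 75, "Na": 75}, {"K": 75, "Na": 75})
        assert infer_permeability_ratio(0.0, sol) == pytest.approx(1.0)

    def test_printed_wild_type_ratio(self, physiological_solutions):
        r = infer_permeability_ratio(-68.4, physiological_solutions)
        assert r == pytest.approx(25.9, abs=0.5)

    def test_hyperselective_mutant_exceeds_50(self, physiological_solutions):
        assert infer_permeability_ratio(-82.0, physiological_solutions) > 50

    def test_reversal_beyond_nernst_raises_not_clamps(self, physiological_solutions):
        # E_rev below the K+ Nernst potential (-91.3 mV) has no positive root
        with pytest.raises(GHKDomainError, match="inconsistent"):
            infer_permeability_ratio(-100.0, physiological_solutions)

    @given(ratio=st.floats(0.05, 200.0),
           ko=st.floats(1.0, 150.0), ki=st.floats(1.0, 150.0),
           nao=st.floats(1.0, 150.0), nai=st.floats(0.0, 150.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_round_trip_inverts_forward_equation(self, ratio, ko, ki, nao, nai):
        # proportional outer/inner solutions make E_rev independent of the
        # ratio (structurally unidentifiable) -- exclude near-degenerate draws
        assume(abs(ko * nai - ki * nao) > 1e-3 * (ko + nao) * (ki + nai))
        sol = SolutionPair({"K": ko, "Na": nao}, {"K": ki, "Na": nai})
        perms = PermeabilitySet(1.0, 1.0 / ratio)
        v = ghk_reversal_voltage(perms, sol)
        assert infer_permeability_ratio(v, sol) == pytest.approx(ratio, rel=1e-9)


class TestEstimateErev:
    @staticmethod
    def _recording(voltages, amps):
        t = np.linspace(0, 3, 300)
        currents = np.zeros((len(voltages), t.size))
        light = (t >= 1.0) & (t <= 2.0)
        for i, a in enumerate(amps):
            currents[i, light] = a
        return IVRecording(t, np.asarray(voltages, float), currents,
                           1.0, 2.0, 100.0)

    def test_symmetric_bracket_interpolates_midpoint(self):
        rec = self._recording([-70, -60], [-5, 5])
        est = estimate_erev(rec, "steady")
        assert est.value_mV == pytest.approx(-65.0)
        assert est.method == "interpolated"
        assert est.bracket_mV == (-70.0, -60.0)

    def test_no_crossing_extrapolates_two_point_line(self):
        # line I = 0.5 (V + 110): root at -110 mV, outside the grid
        v = np.array([-90.0, -80.0, -70.0])
        rec = self._recording(v, 0.5 * (v + 110))
        est = estimate_erev(rec, "steady")
        assert est.method == "extrapolated"
        assert est.value_mV == pytest.approx(-110.0)

    def test_multiple_crossings_listed_in_error(self):
        rec = self._recording([-90, -70, -50, -30], [-5, 5, -5, 5])
        with pytest.raises(ValueError, match="multiple zero crossings"):
            estimate_erev(rec, "steady")

    def test_single_step_rejected(self):
        rec = self._recording([-70], [-5])
        with pytest.raises(ValueError, match="at least 2"):
            estimate_erev(rec, "steady")

    def test_round_trip_against_analytic_reversal(
            self, physiological_solutions, k_selective_perms):
        rec, truth = gen_iv_dataset(k_selective_perms, physiological_solutions,
                                    noise_sd_pA=0.0)
        est = estimate_erev(rec, "steady")
        assert est.value_mV == pytest.approx(truth.params["erev_mV"], abs=5.0)


class TestLowpassGaussian:
    def test_dc_gain_is_unity(self):
        x = np.full(1000, 3.7)
        assert lowpass_gaussian(x, 1000.0, 20000.0) == pytest.approx(x)

    def test_minus_3db_at_cutoff(self):
        fs, fc = 50_000.0, 1000.0
        t = np.arange(0, 0.5, 1 / fs)
        y = lowpass_gaussian(np.sin(2 * np.pi * fc * t), fc, fs)
        gain = y[5000:-5000].std() * math.sqrt(2)
        assert gain == pytest.approx(2 ** -0.5, rel=0.01)

    def test_passband_attenuation_below_one_percent(self):
        fs, fc = 50_000.0, 1000.0
        t = np.arange(0, 0.5, 1 / fs)
        y = lowpass_gaussian(np.sin(2 * np.pi * fc / 10 * t), fc, fs)
        assert y[5000:-5000].std() * math.sqrt(2) > 0.99

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_gaussian(np.zeros(100), 500.0, 1000.0)


class TestPhotocurrentMetrics:
    def test_flat_trace_gives_zero_metrics(self):
        t = np.linspace(0, 3, 3000)
        m = extract_photocurrent_metrics(t, np.zeros_like(t), (1.0, 2.0))
        assert m.baseline_pA == m.peak_pA == m.steady_pA == 0.0

    def test_square_pulse_peak_equals_steady(self):
        t = np.linspace(0, 3, 3000)
        y = np.where((t >= 1.0) & (t <= 2.0), -100.0, 0.0)
        m = extract_photocurrent_metrics(t, y, (1.0, 2.0))
        assert m.peak_pA == pytest.approx(-100.0)
        assert m.steady_pA == pytest.approx(-100.0)

    def test_desensitizing_trace_matches_generator_truth(self):
        t, y, truth = gen_photocurrent(
            [(-80.0, 0.05)], desensitization=(-40.0, 0.05),
            noise_sd_pA=0.5, seed=3)
        m = extract_photocurrent_metrics(t, y, truth.params["light_window_s"])
        assert m.steady_pA == pytest.approx(truth.params["steady_pA"], abs=1.0)
        assert m.peak_pA == pytest.approx(-80.0 - 40.0, rel=0.1)

    def test_light_window_outside_record_rejected(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(ValueError, match="light window"):
            extract_photocurrent_metrics(t, np.zeros_like(t), (0.5, 2.0))


class TestExponentialKinetics:
    def test_single_exponential_recovered_exactly(self):
        t = np.linspace(0, 0.1, 2000)
        y = -50.0 * np.exp(-t / 0.01)
        fit = fit_exponential_kinetics(t, y, 1)
        assert fit.taus[0] == pytest.approx(0.01, rel=1e-3)
        assert fit.amplitudes[0] == pytest.approx(-50.0, rel=1e-3)

    def test_three_separated_components_within_5pct(self):
        taus = np.array([0.001, 0.01, 0.1])
        t = np.linspace(0, 0.6, 8000)
        y = sum(np.exp(-t / tau) for tau in taus)
        fit = fit_exponential_kinetics(t, y, 3)
        assert np.allclose(fit.taus, taus, rtol=0.05)

    def test_noisy_recovery_within_15pct(self, rng):
        # SNR 20 with the fastest decay well sampled (>50 points per tau)
        taus = np.array([0.001, 0.01, 0.1])
        t = np.linspace(0, 0.6, 50_000)
        clean = sum(np.exp(-t / tau) for tau in taus)
        y = clean + rng.normal(0, np.abs(clean).max() / 20, t.size)  # SNR 20
        fit = fit_exponential_kinetics(t, y, 3)
        assert np.allclose(fit.taus, taus, rtol=0.15)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_exponential_kinetics(np.linspace(0, 1, 10), np.zeros(10), 3)


class TestDffMetrics:
    FS = 10.0

    def _time(self, dur=80.0):
        return np.arange(0, dur, 1 / self.FS)

    def test_constant_trace_gives_zero_everywhere(self):
        t = self._time()
        res = compute_dff_metrics(t, np.full_like(t, 50.0), (30.0, 40.0),
                                  sampling_rate_hz=self.FS)
        assert np.allclose(res.dff, 0.0, atol=1e-12)
        assert res.peak_inhibited == pytest.approx(0.0, abs=1e-12)
        assert res.rebound == pytest.approx(0.0, abs=1e-12)

    def test_twenty_percent_step_decrease(self):
        t = self._time()
        f = np.full_like(t, 100.0)
        f[(t >= 30.0) & (t <= 40.0)] = 80.0
        res = compute_dff_metrics(t, f, (30.0, 40.0), sampling_rate_hz=self.FS)
        assert res.peak_inhibited == pytest.approx(-0.20, abs=0.005)

    def test_pure_bleach_flattens_after_detrending(self):
        t = self._time(120.0)
        f = 60.0 * np.exp(-t / 200.0) + 40.0 * np.exp(-t / 30.0)
        res = compute_dff_metrics(t, f, (60.0, 70.0), sampling_rate_hz=self.FS)
        assert isinstance(res, DffResult)
        assert np.abs(res.dff).max() < 0.01

    def test_stimulus_in_first_five_seconds_rejected(self):
        t = self._time()
        with pytest.raises(ValueError, match="pre-stimulus"):
            compute_dff_metrics(t, np.ones_like(t), (2.0, 10.0),
                                sampling_rate_hz=self.FS)
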