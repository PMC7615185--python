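"""Synthetic-data generators with serialized ground truth.

Every input the analysis pipeline consumes can be generated here with a
known ground truth, so each stage is testable without instrument data:
GHK-shaped I-V families with gating and noise, difference-absorption cubes
from a multi-intermediate photocycle, gated multi-exponential
photocurrents, Gaussian-band absorption spectra and pH titrations,
eight-species retinal-oxime chromatograms, two-state conformational
trajectories with ion hydration and site binding, and logistic melting
curves.

Design contract: every generator is a pure function of (parameters, seed);
regeneration with the same inputs is bit-identical. The returned
:class:`SyntheticTruth` captures every ground-truth value needed to score
a recovery test without re-reading generator code. Noise is additive
Gaussian; SNR is defined as peak |signal| / noise SD and written into the
truth record.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .constants import FARADAY, GAS_CONSTANT
from .iontransport import IVRecording, PermeabilitySet, SolutionPair, \
    ghk_reversal_voltage
from .photocycle import (PhotocycleScheme, SpeciesSpectrum,
                         TransientAbsorptionCube, default_hckcr1_scheme,
                         default_species_spectra, propagate_scheme,
                         synthesize_cube)
from .retinal_isomers import DEFAULT_EPSILON_360, IsomerTable
from .spectra import (PRESET_FWHM_NM, SPECTRUM_PRESETS, Spectrum,
                      TitrationSeries, gaussian_band_spectrum)
from .traj import ATOM_COLUMNS, TrajectoryBundle

import pandas as pd

__all__ = [
    "SyntheticTruth", "DEFAULT_SEED",
    "gen_iv_dataset", "gen_transient_absorption", "gen_photocurrent",
    "gen_spectrum", "gen_titration_series", "gen_chromatogram",
    "gen_trajectory", "gen_melting_curve", "ghk_flux_current",
]

DEFAULT_SEED = 20230830

# per-generator offsets give one global seed namespace
_SEED_OFFSETS = {
    "iv": 1, "cube": 2, "photocurrent": 3, "spectrum": 4,
    "titration": 5, "chromatogram": 6, "trajectory": 7, "melting": 8,
}


def _rng(name: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), _SEED_OFFSETS[name]])


@dataclass
class SyntheticTruth:
    """Generator name, full ground-truth parameter map, and seed."""

    generator: str
    params: dict
    seed: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


# ---------------------------------------------------------------------------
# electrophysiology
# ---------------------------------------------------------------------------

def ghk_flux_current(v_mV: np.ndarray, perms: PermeabilitySet,
                     sol: SolutionPair) -> np.ndarray:
    """Constant-field (GHK flux) current, arbitrary units, for K/Na/Cl.

    I(V) = sum_ion p z^2 u ([X]i - [X]o e^(-z u)) / (1 - e^(-z u)),
    u = V F / (R T). Its zero coincides analytically with the GHK voltage
    equation's reversal potential. This flux form is a generator-side
    assumption only; the analysis side never depends on it.
    """
    v = np.asarray(v_mV, dtype=float) * 1e-3
    u = v * FARADAY / (GAS_CONSTANT * sol.temperature)
    total = np.zeros_like(u)
    for ion, z, p in (("K", 1, perms.p_K), ("Na", 1, perms.p_Na),
                      ("Cl", -1, perms.p_Cl)):
        if p == 0:
            continue
        ci, co = sol.conc("inner", ion), sol.conc("outer", ion)
        zu = z * u
        small = np.abs(zu) < 1e-6
        ez = np.exp(-zu)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(small, ci - co + 0.5 * zu * (ci + co),
                            zu * (ci - co * ez) / (1.0 - ez))
        total = total + p * z * frac  # z (not z^2): keeps anion current signed
    return total


def gen_iv_dataset(true_perms: PermeabilitySet, sol: SolutionPair,
                   voltages_mV: np.ndarray | None = None, *,
                   gmax_pA: float = 10.0, noise_sd_pA: float = 0.0,
                   seed: int = DEFAULT_SEED,
                   sampling_rate_hz: float = 1000.0,
                   light_window_s: tuple[float, float] = (1.0, 2.0),
                   duration_s: float = 3.0,
                   tau_act_s: float = 0.01,
                   tau_off_s: float = 0.02) -> tuple[IVRecording, SyntheticTruth]:
    """GHK-flux I-V family with mono-exponential gating and Gaussian noise.

    Per-step steady current follows the constant-field flux equation scaled
    by ``gmax_pA`` per 100 mM of driving concentration; light gating turns
    it on with time constant ``tau_act_s`` and off with ``tau_off_s``.
    The zero-current voltage of the noiseless family equals the analytic
    GHK reversal potential.
    """
    if voltages_mV is None:
        voltages_mV = np.arange(-96.0, 4.0 + 1e-9, 10.0)
    voltages_mV = np.asarray(voltages_mV, dtype=float)
    if np.any(np.abs(voltages_mV) > 150):
        raise ValueError("voltage grid must stay within +/-150 mV")
    rng = _rng("iv", seed)
    t = np.arange(0.0, duration_s, 1.0 / sampling_rate_hz)
    t_on, t_off = light_window_s
    steady = gmax_pA / 100.0 * ghk_flux_current(voltages_mV, true_perms, sol)
    gate = np.zeros_like(t)
    on = (t >= t_on) & (t <= t_off)
    gate[on] = 1.0 - np.exp(-(t[on] - t_on) / tau_act_s)
    after = t > t_off
    g_end = 1.0 - math.exp(-(t_off - t_on) / tau_act_s)
    gate[after] = g_end * np.exp(-(t[after] - t_off) / tau_off_s)
    currents = steady[:, None] * gate[None, :]
    if noise_sd_pA > 0:
        currents = currents + rng.normal(0.0, noise_sd_pA, currents.shape)
    rec = IVRecording(t, voltages_mV, currents, t_on, t_off, sampling_rate_hz,
                      junction_corrected=True)
    erev = ghk_reversal_voltage(true_perms, sol)
    truth = SyntheticTruth("gen_iv_dataset", {
        "p_K": true_perms.p_K, "p_Na": true_perms.p_Na, "p_Cl": true_perms.p_Cl,
        "outer_mM": sol.outer, "inner_mM": sol.inner,
        "temperature_K": sol.temperature, "gmax_pA": gmax_pA,
        "noise_sd_pA": noise_sd_pA, "voltages_mV": voltages_mV,
        "light_window_s": light_window_s, "tau_act_s": tau_act_s,
        "tau_off_s": tau_off_s, "erev_mV": erev,
    }, seed)
    return rec, truth


# ---------------------------------------------------------------------------
# photocycle
# ---------------------------------------------------------------------------

def gen_transient_absorption(scheme: PhotocycleScheme | None = None, *,
                             spectra: dict[str, SpeciesSpectrum] | None = None,
                             times_s: np.ndarray | None = None,
                             snr: float | None = None,
                             seed: int = DEFAULT_SEED,
                             n_averaged: int = 50
                             ) -> tuple[TransientAbsorptionCube, SyntheticTruth]:
    """Difference-absorption cube from a photocycle scheme plus noise.

    Defaults: the two-parallel-chain eight-intermediate scheme with
    Gaussian species difference bands, a log-spaced 1 us - 10 s time grid.
    ``snr`` is peak |dA| / noise SD; ``None`` means noiseless.
    """
    scheme = scheme or default_hckcr1_scheme()
    spectra = spectra or default_species_spectra()
    if times_s is None:
        # 400 points per decade over 1 us - 10 s: the density of a
        # log-rebinned digitizer trace, which is what makes the eight
        # interleaved rate constants statistically resolvable at SNR ~30
        times_s = np.logspace(-6, 1, 2801)
    rng = _rng("cube", seed)
    C = propagate_scheme(scheme, times_s)
    cube = synthesize_cube(scheme, C, times_s, spectra, n_averaged)
    noise_sd = 0.0
    if snr is not None and np.isfinite(snr):
        peak = float(np.abs(cube.delta_A).max())
        noise_sd = peak / snr
        cube.delta_A = cube.delta_A + rng.normal(0.0, noise_sd, cube.delta_A.shape)
    truth = SyntheticTruth("gen_transient_absorption", {
        "species": list(scheme.species),
        "rates_s": {f"{a}->{b}": k for (a, b), k in scheme.rates.items()},
        "initial": scheme.initial, "snr": snr, "noise_sd": noise_sd,
        "relaxation_rates_s": scheme.relaxation_rates(),
        "n_spectrally_distinct": len(spectra),
    }, seed)
    return cube, truth


def gen_photocurrent(components: list[tuple[float, float]], *,
                     light_window_s: tuple[float, float] = (0.1, 1.1),
                     duration_s: float = 3.0,
                     sampling_rate_hz: float = 10_000.0,
                     tau_act_s: float = 0.002,
                     desensitization: tuple[float, float] | None = None,
                     noise_sd_pA: float = 0.0,
                     seed: int = DEFAULT_SEED
                     ) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Gated multi-exponential photocurrent trace.

    ``components`` are (amplitude_pA, tau_off_s) pairs defining the
    light-off decay; their amplitude sum is the steady light-on level.
    Optional ``desensitization`` = (extra_peak_pA, tau_des_s) adds an
    early decaying peak during illumination. Returns (time, trace, truth).
    """
    for _, tau in components:
        if tau <= 0:
            raise ValueError("off time constants must be > 0")
    rng = _rng("photocurrent", seed)
    t = np.arange(0.0, duration_s, 1.0 / sampling_rate_hz)
    t_on, t_off = light_window_s
    amp = sum(a for a, _ in components)
    y = np.zeros_like(t)
    on = (t >= t_on) & (t <= t_off)
    dt_on = t[on] - t_on
    level = amp
    y[on] = amp * (1.0 - np.exp(-dt_on / tau_act_s))
    if desensitization is not None:
        d_amp, tau_des = desensitization
        y[on] += d_amp * np.exp(-dt_on / tau_des) * (1.0 - np.exp(-dt_on / tau_act_s))
    after = t > t_off
    y_off0 = y[on][-1] if on.any() else 0.0
    scale = y_off0 / amp if amp != 0 else 0.0
    dt_off = t[after] - t_off
    y[after] = scale * sum(a * np.exp(-dt_off / tau) for a, tau in components)
    if noise_sd_pA > 0:
        y = y + rng.normal(0.0, noise_sd_pA, y.shape)
    truth = SyntheticTruth("gen_photocurrent", {
        "components": components, "light_window_s": light_window_s,
        "tau_act_s": tau_act_s, "desensitization": desensitization,
        "steady_pA": level, "noise_sd_pA": noise_sd_pA,
        "sampling_rate_hz": sampling_rate_hz,
    }, seed)
    return t, y, truth


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def gen_spectrum(preset: str | None = None, *, lmax_nm: float | None = None,
                 fwhm_nm: float = PRESET_FWHM_NM, peak_au: float = 1.0,
                 noise_sd_au: float = 0.0, seed: int = DEFAULT_SEED
                 ) -> tuple[Spectrum, SyntheticTruth]:
    """Gaussian-band absorption spectrum, from a named preset or explicit lmax.

    Presets carry the measured dark-state lambda_max of the HcKCR pigments
    (band shape synthetic): hckcr1_wt_dark 521 nm, hckcr2_wt_dark 486 nm,
    hckcr1_d105n 508 nm, hckcr1_d229n 386 nm.
    """
    if (preset is None) == (lmax_nm is None):
        raise ValueError("give exactly one of preset or lmax_nm")
    if preset is not None:
        if preset not in SPECTRUM_PRESETS:
            raise ValueError(f"unknown preset {preset!r}; "
                             f"known: {sorted(SPECTRUM_PRESETS)}")
        lmax_nm = SPECTRUM_PRESETS[preset]
    rng = _rng("spectrum", seed)
    spec = gaussian_band_spectrum(lmax_nm, fwhm_nm=fwhm_nm, peak_au=peak_au,
                                  label=preset or f"lmax={lmax_nm:g}nm")
    if noise_sd_au > 0:
        spec.absorbance = spec.absorbance + rng.normal(
            0.0, noise_sd_au, spec.absorbance.shape)
    truth = SyntheticTruth("gen_spectrum", {
        "preset": preset, "lmax_nm": lmax_nm, "fwhm_nm": fwhm_nm,
        "peak_au": peak_au, "noise_sd_au": noise_sd_au,
    }, seed)
    return spec, truth


def gen_titration_series(*, pka: float = 4.0, hill: float = 1.0,
                         a_acid: float = 1.0, a_base: float = 0.05,
                         lmax_nm: float = 521.0,
                         ph_values: np.ndarray | None = None,
                         noise_sd_au: float = 0.0,
                         seed: int = DEFAULT_SEED
                         ) -> tuple[TitrationSeries, SyntheticTruth]:
    """Absorption spectra over a pH series following a Hill sigmoid.

    The band amplitude at ``lmax_nm`` follows
    A(pH) = a_acid + (a_base - a_acid) / (1 + 10^(hill*(pka - pH))); the
    readout wavelength defaults to the acid-form band center.
    """
    if ph_values is None:
        ph_values = np.arange(2.0, 12.0)
    ph_values = np.asarray(ph_values, dtype=float)
    rng = _rng("titration", seed)
    spectra = []
    for ph in ph_values:
        amp = a_acid + (a_base - a_acid) / (1.0 + 10.0 ** (hill * (pka - ph)))
        sp = gaussian_band_spectrum(lmax_nm, peak_au=amp, label=f"pH {ph:g}")
        if noise_sd_au > 0:
            sp.absorbance = sp.absorbance + rng.normal(
                0.0, noise_sd_au, sp.absorbance.shape)
        spectra.append(sp)
    series = TitrationSeries(ph_values, spectra, readout_nm=lmax_nm)
    truth = SyntheticTruth("gen_titration_series", {
        "pka": pka, "hill": hill, "a_acid": a_acid, "a_base": a_base,
        "lmax_nm": lmax_nm, "ph_values": ph_values, "noise_sd_au": noise_sd_au,
    }, seed)
    return series, truth


# ---------------------------------------------------------------------------
# chromatograms
# ---------------------------------------------------------------------------

def gen_chromatogram(composition: dict[str, float], *,
                     table: IsomerTable | None = None,
                     retention_min: dict[str, float] | None = None,
                     sigma_min: float = 0.15, area_scale: float = 1e-4,
                     noise_sd_au: float = 0.0, dt_min: float = 0.01,
                     seed: int = DEFAULT_SEED):
    """Gaussian-peak oxime chromatogram whose unmixing inverts exactly.

    Peak areas are composition_i * eps360_i * area_scale, so the
    1/eps-weighted unmixing recovers ``composition``. Returns
    (time_min, absorbance, windows, truth); windows span +/-5 sigma per peak.
    """
    table = table or IsomerTable()
    if abs(sum(composition.values()) - 1.0) > 1e-9:
        raise ValueError("composition fractions must sum to 1")
    names = list(composition)
    if retention_min is None:
        retention_min = {n: 4.0 + 3.0 * i for i, n in enumerate(names)}
    rng = _rng("chromatogram", seed)
    t_end = max(retention_min.values()) + 3.0
    t = np.arange(0.0, t_end, dt_min)
    a = np.zeros_like(t)
    areas = {}
    for n in names:
        area = composition[n] * table.epsilon_360[n] * area_scale
        areas[n] = area
        amp = area / (sigma_min * math.sqrt(2.0 * math.pi))
        a += amp * np.exp(-0.5 * ((t - retention_min[n]) / sigma_min) ** 2)
    if noise_sd_au > 0:
        a = a + rng.normal(0.0, noise_sd_au, a.shape)
    windows = {n: (retention_min[n] - 5 * sigma_min,
                   retention_min[n] + 5 * sigma_min) for n in names}
    truth = SyntheticTruth("gen_chromatogram", {
        "composition": composition, "areas": areas,
        "retention_min": retention_min, "sigma_min": sigma_min,
        "area_scale": area_scale, "noise_sd_au": noise_sd_au,
    }, seed)
    return t, a, windows, truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _water_directions(rng, n_total: int) -> np.ndarray:
    """Persistent unit direction per water (fixed for the trajectory)."""
    v = rng.normal(size=(n_total, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _place_waters(rng, center: np.ndarray, dirs: np.ndarray, n_close: int,
                  shell_A: float, far_A: float) -> np.ndarray:
    """n_close waters on the first shell around center, the rest far away."""
    r = np.where(np.arange(dirs.shape[0]) < n_close, shell_A, far_A)
    return center + r[:, None] * dirs + rng.normal(0.0, 0.05, dirs.shape)


def gen_trajectory(n_frames: int = 1000, *,
                   d_tight_A: float = 4.0, d_loose_A: float = 8.0,
                   k_tight_to_loose: float = 0.02,
                   k_loose_to_tight: float = 0.05,
                   start_state: str = "tight",
                   jitter_A: float = 0.2,
                   n_waters: int = 6,
                   hydration_counts: dict[str, int] | None = None,
                   hydration_shell_A: float = 2.8,
                   binding_schedule: list[tuple[int, int]] | None = None,
                   site_contact_A: float = 2.8,
                   frame_interval_ps: float = 200.0,
                   seed: int = DEFAULT_SEED
                   ) -> tuple[TrajectoryBundle, SyntheticTruth]:
    """Minimal synthetic trajectory with two-state side-chain dynamics.

    Topology: a probe atom pair (TYR 222 OH moving against TRP 102 CZ2 at
    the origin), one K+ ion, ``n_waters`` water oxygens, and a binding
    site (ASP 116 OD1 / THR 120 OG1). The probe distance follows a
    two-state continuous-time Markov chain (rates in 1/frame) with
    Gaussian jitter around the tight/loose means, so the stationary tight
    fraction is k_loose_to_tight / (k_tight_to_loose + k_loose_to_tight).
    During scheduled binding intervals the ion sits ``site_contact_A``
    from the site with ``hydration_counts['bound']`` first-shell waters;
    otherwise it floats far from the site with
    ``hydration_counts['unbound']`` shell waters.
    """
    if not d_tight_A < d_loose_A:
        raise ValueError("d_tight_A must be below d_loose_A")
    hyd = {"bound": 2, "unbound": min(6, n_waters)}
    if hydration_counts:
        hyd.update(hydration_counts)
    if max(hyd.values()) > n_waters:
        raise ValueError("hydration count exceeds n_waters")
    binding_schedule = binding_schedule or []
    rng = _rng("trajectory", seed)

    # exact discrete-time transition probabilities of the 2-state CTMC
    s = k_tight_to_loose + k_loose_to_tight
    if s > 0:
        decay = 1.0 - math.exp(-s)
        p_tl = k_tight_to_loose / s * decay
        p_lt = k_loose_to_tight / s * decay
    else:
        p_tl = p_lt = 0.0
    states = np.empty(n_frames, dtype=bool)  # True = tight
    state = start_state == "tight"
    u = rng.random(n_frames)
    for f in range(n_frames):
        states[f] = state
        p_switch = p_tl if state else p_lt
        if u[f] < p_switch:
            state = not state

    rows = []

    def add(name, resname, resnum, element, chain="A"):
        rows.append({"index": len(rows), "name": name, "resname": resname,
                     "resnum": resnum, "chain": chain, "element": element})

    add("CZ2", "TRP", 102, "C")
    add("OH", "TYR", 222, "O")
    add("K", "K", 300, "K")
    for i in range(n_waters):
        add("O", "HOH", 400 + i, "O")
    add("OD1", "ASP", 116, "O")
    add("OG1", "THR", 120, "O")
    atoms = pd.DataFrame(rows, columns=list(ATOM_COLUMNS))

    site_center = np.array([30.0, 0.0, 0.0])
    bound_mask = np.zeros(n_frames, dtype=bool)
    for a, b in binding_schedule:
        bound_mask[a:b + 1] = True

    coords = np.zeros((n_frames, len(atoms), 3))
    d_probe = np.where(states, d_tight_A, d_loose_A) + rng.normal(
        0.0, jitter_A, n_frames)
    dirs = _water_directions(rng, n_waters)
    for f in range(n_frames):
        coords[f, 0] = 0.0  # TRP anchor
        coords[f, 1] = [d_probe[f], 0.0, 0.0]
        if bound_mask[f]:
            ion = site_center + np.array([site_contact_A, 0.0, 0.0])
            n_close = hyd["bound"]
        else:
            ion = site_center + np.array([20.0, 0.0, 0.0])
            n_close = hyd["unbound"]
        ion = ion + rng.normal(0.0, 0.02, 3)
        coords[f, 2] = ion
        coords[f, 3:3 + n_waters] = _place_waters(
            rng, ion, dirs, n_close, hydration_shell_A, far_A=12.0)
        coords[f, 3 + n_waters] = site_center
        coords[f, 4 + n_waters] = site_center + np.array([0.0, 3.0, 0.0])

    # generator coordinates are unwrapped by construction; scheduled binding
    # teleports the ion, which would trip the wrap heuristic spuriously
    bundle = TrajectoryBundle(atoms, coords, frame_interval_ps,
                              check_wrapping=False)
    stationary = (k_loose_to_tight / s) if s > 0 else (1.0 if start_state == "tight" else 0.0)
    truth = SyntheticTruth("gen_trajectory", {
        "n_frames": n_frames, "d_tight_A": d_tight_A, "d_loose_A": d_loose_A,
        "k_tight_to_loose": k_tight_to_loose,
        "k_loose_to_tight": k_loose_to_tight,
        "stationary_tight_fraction": stationary,
        "realized_tight_fraction": float(states.mean()),
        "jitter_A": jitter_A, "hydration_counts": hyd,
        "hydration_shell_A": hydration_shell_A,
        "binding_schedule": binding_schedule,
        "bound_fraction": float(bound_mask.mean()),
        "site_contact_A": site_contact_A,
        "frame_interval_ps": frame_interval_ps,
    }, seed)
    return bundle, truth


# ---------------------------------------------------------------------------
# melting curves
# ---------------------------------------------------------------------------

def gen_melting_curve(*, tm_C: float = 60.0, width_C: float = 3.0,
                      upper: float = 1.0, lower: float = 0.0,
                      temperatures_C: np.ndarray | None = None,
                      noise_sd: float = 0.0, seed: int = DEFAULT_SEED):
    """4-parameter logistic thermostability series (response falls with T).

    Default temperature grid: 4 degC reference plus 20-95 degC in 5 degC
    steps, emulating an FSEC-TS experiment. Returns (T, response, truth).
    """
    if temperatures_C is None:
        temperatures_C = np.concatenate([[4.0], np.arange(20.0, 96.0, 5.0)])
    temperatures_C = np.asarray(temperatures_C, dtype=float)
    rng = _rng("melting", seed)
    y = lower + (upper - lower) / (1.0 + np.exp((temperatures_C - tm_C) / width_C))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.shape)
    truth = SyntheticTruth("gen_melting_curve", {
        "tm_C": tm_C, "width_C": width_C, "upper": upper, "lower": lower,
        "temperatures_C": temperatures_C, "noise_sd": noise_sd,
    }, seed)
    return temperatures_C, y, truth
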