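"""Electrophysiology analytics for light-gated K+ channels.

This module turns voltage-clamp recordings into reversal potentials and
Goldman-Hodgkin-Katz (GHK) permeability ratios, and provides photocurrent
kinetics and fiber-photometry dF/F metrics.

The GHK voltage equation used throughout (concentrations in mM, activities
taken equal to concentrations) is::

    V_rev = (RT/F) * ln[ (pK*[K]o + pNa*[Na]o + pCl*[Cl]i)
                       / (pK*[K]i + pNa*[Na]i + pCl*[Cl]o) ]

with the chloride terms in the standard convention (internal Cl in the
numerator because its charge is negative). Divalent ions are tracked in
solution definitions but never enter the quotient. With a single permeant
cation pair and P_Cl = 0 the equation inverts algebraically, which is how
reversal potentials measured under bi-ionic conditions are converted to
P_K/P_Na ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .constants import (DEFAULT_TEMPERATURE_K, FARADAY, GAS_CONSTANT,
                        KNOWN_IONS)
from ._exponential import ExponentialFit, ExponentialFitError, fit_multiexponential

__all__ = [
    "SolutionPair", "PermeabilitySet", "IVRecording", "ErevEstimate",
    "PhotocurrentMetrics", "DffResult", "GHKDomainError",
    "ghk_reversal_voltage", "infer_permeability_ratio", "estimate_erev",
    "lowpass_gaussian", "extract_photocurrent_metrics",
    "fit_exponential_kinetics", "compute_dff_metrics",
]


class GHKDomainError(ValueError):
    """Raised when a GHK quotient or its inversion leaves the valid domain."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _validate_solution(side: str, conc: dict[str, float]) -> dict[str, float]:
    out = {}
    for name, c in conc.items():
        if name not in KNOWN_IONS:
            raise ValueError(
                f"unknown ion {name!r} in {side} solution; "
                f"accepted names: {sorted(KNOWN_IONS)}"
            )
        c = float(c)
        if c < 0 or not math.isfinite(c):
            raise ValueError(f"{side} [{name}] must be finite and >= 0, got {c}")
        out[name] = c
    return out


@dataclass(frozen=True)
class SolutionPair:
    """Ionic compositions (mM) on both membrane faces plus temperature (K).

    Missing ions default to 0 mM; in particular [Na]i defaults to 0 for a
    K-gluconate internal unless stated explicitly.
    """

    outer: dict[str, float]
    inner: dict[str, float]
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        object.__setattr__(self, "outer", _validate_solution("outer", self.outer))
        object.__setattr__(self, "inner", _validate_solution("inner", self.inner))
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    def conc(self, side: str, ion: str) -> float:
        d = self.outer if side == "outer" else self.inner
        return d.get(ion, 0.0)

    @property
    def rt_over_f_mV(self) -> float:
        """Thermal voltage RT/F in millivolts."""
        return GAS_CONSTANT * self.temperature / FARADAY * 1e3


@dataclass(frozen=True)
class PermeabilitySet:
    """Relative permeabilities with one entry fixed at 1 as the reference."""

    p_K: float = 1.0
    p_Na: float = 0.0
    p_Cl: float = 0.0
    reference: str = "K"

    def __post_init__(self):
        for name, v in (("p_K", self.p_K), ("p_Na", self.p_Na), ("p_Cl", self.p_Cl)):
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        ref_val = {"K": self.p_K, "Na": self.p_Na, "Cl": self.p_Cl}.get(self.reference)
        if ref_val is None:
            raise ValueError(f"reference must be one of K/Na/Cl, got {self.reference!r}")
        if not math.isclose(ref_val, 1.0, rel_tol=1e-12):
            raise ValueError(
                f"reference permeability p_{self.reference} must equal 1, got {ref_val}"
            )


@dataclass
class IVRecording:
    """Per-voltage-step current traces sharing one time grid.

    ``currents_pA`` has shape (n_steps, n_samples); ``voltages_mV`` must be
    strictly increasing. The light window must lie inside the record.
    """

    time_s: np.ndarray
    voltages_mV: np.ndarray
    currents_pA: np.ndarray
    light_on_s: float
    light_off_s: float
    sampling_rate_hz: float
    junction_corrected: bool = False

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.voltages_mV = np.asarray(self.voltages_mV, dtype=float)
        self.currents_pA = np.atleast_2d(np.asarray(self.currents_pA, dtype=float))
        if np.any(np.diff(self.voltages_mV) <= 0):
            raise ValueError("voltage steps must be strictly increasing")
        if self.currents_pA.shape != (self.voltages_mV.size, self.time_s.size):
            raise ValueError(
                f"currents shape {self.currents_pA.shape} does not match "
                f"({self.voltages_mV.size} steps, {self.time_s.size} samples)"
            )
        if not (self.time_s[0] <= self.light_on_s < self.light_off_s <= self.time_s[-1]):
            raise ValueError("light window must lie inside the recorded interval")


@dataclass(frozen=True)
class ErevEstimate:
    """Reversal potential with provenance of how it was obtained."""

    value_mV: float
    method: str  # "interpolated" | "extrapolated"
    bracket_mV: tuple[float, float]
    junction_corrected: bool = False

    def __post_init__(self):
        if self.method not in ("interpolated", "extrapolated"):
            raise ValueError(f"method must be interpolated/extrapolated, got {self.method!r}")
        if self.method == "interpolated":
            lo, hi = sorted(self.bracket_mV)
            if not lo <= self.value_mV <= hi:
                raise ValueError("interpolated E_rev must lie between its bracket")


@dataclass
class PhotocurrentMetrics:
    baseline_pA: float
    peak_pA: float
    steady_pA: float
    tau_on: ExponentialFit | None = None
    tau_off: ExponentialFit | None = None


@dataclass
class DffResult:
    dff: np.ndarray
    baseline_F: float
    peak_inhibited: float
    rebound: float
    bleach_fit: ExponentialFit | None = None


# ---------------------------------------------------------------------------
# GHK algebra
# ---------------------------------------------------------------------------

def ghk_reversal_voltage(perms: PermeabilitySet, sol: SolutionPair) -> float:
    """Reversal potential (mV) from the GHK voltage equation.

    Only K, Na and Cl enter; activities equal concentrations.
    """
    num = (perms.p_K * sol.conc("outer", "K")
           + perms.p_Na * sol.conc("outer", "Na")
           + perms.p_Cl * sol.conc("inner", "Cl"))
    den = (perms.p_K * sol.conc("inner", "K")
           + perms.p_Na * sol.conc("inner", "Na")
           + perms.p_Cl * sol.conc("outer", "Cl"))
    if perms.p_K == 0 and perms.p_Na == 0:
        raise GHKDomainError("at least one cation permeability must be > 0")
    if den <= 0:
        raise GHKDomainError(
            "GHK denominator (pK*[K]i + pNa*[Na]i + pCl*[Cl]o) is "
            f"{den:g}; the reversal potential is undefined"
        )
    if num <= 0:
        raise GHKDomainError(
            "GHK numerator (pK*[K]o + pNa*[Na]o + pCl*[Cl]i) is "
            f"{num:g}; the reversal potential is undefined"
        )
    return sol.rt_over_f_mV * math.log(num / den)


def infer_permeability_ratio(erev_mV: float, sol: SolutionPair) -> float:
    """P_K/P_Na from a measured reversal potential, with P_Cl fixed at 0.

    Exact algebraic inversion of the two-cation GHK voltage equation::

        r = ([Na]o - e*[Na]i) / (e*[K]i - [K]o),  e = exp(V*F/(R*T))

    Raises :class:`GHKDomainError` with a diagnostic (never a clamped value)
    when the gradients are inconsistent with the measured reversal.
    """
    ko, ki = sol.conc("outer", "K"), sol.conc("inner", "K")
    nao, nai = sol.conc("outer", "Na"), sol.conc("inner", "Na")
    if ko == ki == 0 or (nao == nai == 0):
        raise GHKDomainError("solutions must contain K and Na entries on at least one face")
    e = math.exp(erev_mV / sol.rt_over_f_mV)
    den = e * ki - ko
    num = nao - e * nai
    if den == 0:
        if num == 0:
            # fully symmetric condition: every ratio satisfies the
            # equation; report the symmetric solution
            return 1.0
        raise GHKDomainError(
            f"E_rev = {erev_mV:g} mV equals the K+ Nernst potential; "
            "P_K/P_Na is infinite (denominator e*[K]i - [K]o = 0)"
        )
    ratio = num / den
    if ratio < 0 or not math.isfinite(ratio):
        raise GHKDomainError(
            f"ion gradients are inconsistent with E_rev = {erev_mV:g} mV: "
            f"GHK inversion gives P_K/P_Na = {ratio:g}"
        )
    return ratio


# ---------------------------------------------------------------------------
# I-V analysis
# ---------------------------------------------------------------------------

def estimate_erev(rec: IVRecording, measure: str = "peak") -> ErevEstimate:
    """Zero-current crossing of the light-evoked I-V relation.

    Per-step photocurrent amplitudes (``measure`` = ``"peak"`` or
    ``"steady"``) build the I-V table. A single sign change is resolved by
    piecewise-linear interpolation between the bracketing steps; if no sign
    change exists the two steps nearest zero current define a linear
    extrapolation, flagged in the result. Multiple crossings raise an error
    listing all of them rather than silently picking one.
    """
    if measure not in ("peak", "steady"):
        raise ValueError(f"measure must be 'peak' or 'steady', got {measure!r}")
    if rec.voltages_mV.size < 2:
        raise ValueError("need at least 2 voltage steps to locate a reversal")
    amps = np.empty(rec.voltages_mV.size)
    for i in range(amps.size):
        m = extract_photocurrent_metrics(
            rec.time_s, rec.currents_pA[i], (rec.light_on_s, rec.light_off_s))
        amps[i] = m.peak_pA if measure == "peak" else m.steady_pA

    v = rec.voltages_mV
    sign_change = np.flatnonzero(np.signbit(amps[:-1]) != np.signbit(amps[1:]))
    # an exact zero at a grid point counts as its own crossing
    exact = np.flatnonzero(amps == 0.0)
    if exact.size:
        crossings = [float(v[i]) for i in exact]
        if len(crossings) == 1 and sign_change.size == 0:
            return ErevEstimate(crossings[0], "interpolated",
                                (float(v[exact[0]]), float(v[exact[0]])),
                                rec.junction_corrected)
    if sign_change.size > 1:
        xs = [float(v[i] - amps[i] * (v[i + 1] - v[i]) / (amps[i + 1] - amps[i]))
              for i in sign_change]
        raise ValueError(
            "non-monotone I-V relation with multiple zero crossings at "
            + ", ".join(f"{x:.2f} mV" for x in xs)
        )
    if sign_change.size == 1:
        i = int(sign_change[0])
        x = v[i] - amps[i] * (v[i + 1] - v[i]) / (amps[i + 1] - amps[i])
        return ErevEstimate(float(x), "interpolated", (float(v[i]), float(v[i + 1])),
                            rec.junction_corrected)
    # no crossing: extrapolate from the two steps nearest zero current
    order = np.argsort(np.abs(amps))[:2]
    i, j = sorted(int(k) for k in order)
    slope = (amps[j] - amps[i]) / (v[j] - v[i])
    if slope == 0:
        raise ValueError("flat I-V relation; reversal potential undefined")
    x = v[i] - amps[i] / slope
    return ErevEstimate(float(x), "extrapolated", (float(v[i]), float(v[j])),
                        rec.junction_corrected)


# ---------------------------------------------------------------------------
# signal conditioning and metrics
# ---------------------------------------------------------------------------

def lowpass_gaussian(trace: np.ndarray, cutoff_hz: float,
                     sampling_rate_hz: float) -> np.ndarray:
    """Gaussian low-pass whose response passes -3 dB at ``cutoff_hz``.

    The continuous Gaussian kernel has |H(f)| = exp(-2 pi^2 sigma^2 f^2),
    so sigma_t = sqrt(ln 2) / (2*pi*fc) gives |H(fc)| = 2**-0.5 exactly.
    Edges are handled by reflection.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff_hz >= sampling_rate_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist "
            f"({sampling_rate_hz / 2} Hz)"
        )
    sigma_t = math.sqrt(math.log(2)) / (2 * math.pi * cutoff_hz)
    sigma_samples = sigma_t * sampling_rate_hz
    return gaussian_filter1d(np.asarray(trace, dtype=float), sigma_samples,
                             mode="reflect")


def extract_photocurrent_metrics(time_s: np.ndarray, trace_pA: np.ndarray,
                                 light_window: tuple[float, float]) -> PhotocurrentMetrics:
    """Baseline, peak and steady-state photocurrent for one sweep.

    Baseline is the pre-light mean; peak is the extremum of largest
    magnitude during light; steady-state is the mean of the final 10% of
    the light window. Peak and steady are baseline-subtracted with sign
    preserved (inward currents stay negative).
    """
    time_s = np.asarray(time_s, dtype=float)
    trace_pA = np.asarray(trace_pA, dtype=float)
    t_on, t_off = light_window
    if not (time_s[0] <= t_on < t_off <= time_s[-1]):
        raise ValueError("light window lies outside the record")
    pre = trace_pA[time_s < t_on]
    if pre.size == 0:
        raise ValueError("no baseline segment before light onset")
    baseline = float(pre.mean())
    in_light = (time_s >= t_on) & (time_s <= t_off)
    seg = trace_pA[in_light] - baseline
    peak = float(seg[np.argmax(np.abs(seg))])
    t_light = time_s[in_light]
    tail = seg[t_light >= t_off - 0.1 * (t_off - t_on)]
    steady = float(tail.mean())
    return PhotocurrentMetrics(baseline_pA=baseline, peak_pA=peak, steady_pA=steady)


def fit_exponential_kinetics(time_s: np.ndarray, segment: np.ndarray,
                             n_components: int = 3, *,
                             seed: int = 20230830) -> ExponentialFit:
    """Least-squares multi-exponential fit of a photocurrent segment.

    Offset plus up to three exponential terms, optimized by Nelder-Mead
    simplex over log time constants with 8 log-spaced multi-starts and
    linear profiling of the amplitudes. Time constants come back sorted
    ascending.
    """
    return fit_multiexponential(time_s, segment, n_components, seed=seed)


# ---------------------------------------------------------------------------
# fiber-photometry dF/F
# ---------------------------------------------------------------------------

def compute_dff_metrics(time_s: np.ndarray, fluorescence: np.ndarray,
                        stim_window: tuple[float, float], *,
                        sampling_rate_hz: float,
                        baseline_s: float = 5.0,
                        rebound_s: float = 10.0,
                        lowpass_hz: float = 0.5,
                        detrend: bool = True,
                        clip_quantile: float | None = None,
                        seed: int = 20230830) -> DffResult:
    """dF/F with double-exponential bleach correction and inhibition metrics.

    A double-exponential photobleaching trend is fitted on samples outside
    the stimulation and rebound windows (optionally clipped at
    ``clip_quantile`` to suppress residual positive transients; off by
    default since clipping also distorts a genuinely decaying baseline)
    and subtracted while preserving the mean fluorescence level. The corrected series is low-pass
    filtered at ``lowpass_hz``, then dF/F = (F - F0)/F0 with F0 the mean of
    the ``baseline_s`` seconds before stimulation. Peak-inhibited amplitude
    is the minimum dF/F during stimulation minus the baseline dF/F; rebound
    is the maximum during the ``rebound_s`` seconds after stimulus offset.
    """
    time_s = np.asarray(time_s, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    t_on, t_off = stim_window
    if t_on - time_s[0] < baseline_s:
        raise ValueError(
            f"stimulation at {t_on} s leaves less than {baseline_s} s of "
            "pre-stimulus data for the baseline"
        )
    corrected = f.astype(float)
    bleach = None
    if detrend:
        quiet = (time_s < t_on) | (time_s > t_off + rebound_s)
        yq = f[quiet]
        fit_y = yq
        if clip_quantile is not None:
            fit_y = np.minimum(yq, np.quantile(yq, clip_quantile))
        try:
            bleach = fit_multiexponential(time_s[quiet], fit_y, 2, seed=seed)
            trend = bleach.predict(time_s - time_s[quiet][0])
            corrected = f - trend + float(trend.mean())
        except (ExponentialFitError, ValueError) as exc:  # pragma: no cover
            warnings.warn(f"bleach detrend skipped: {exc}")
    if lowpass_hz and lowpass_hz < sampling_rate_hz / 2:
        corrected = lowpass_gaussian(corrected, lowpass_hz, sampling_rate_hz)
    base_mask = (time_s >= t_on - baseline_s) & (time_s < t_on)
    f0 = float(corrected[base_mask].mean())
    if f0 == 0:
        raise ValueError("baseline fluorescence is zero; dF/F undefined")
    dff = (corrected - f0) / f0
    base_dff = float(dff[base_mask].mean())
    stim_mask = (time_s >= t_on) & (time_s <= t_off)
    reb_mask = (time_s > t_off) & (time_s <= t_off + rebound_s)
    peak_inh = float(dff[stim_mask].min() - base_dff)
    rebound = float(dff[reb_mask].max() - base_dff) if reb_mask.any() else 0.0
    return DffResult(dff=dff, baseline_F=f0, peak_inhibited=peak_inh,
                     rebound=rebound, bleach_fit=bleach)
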