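"""Absorption-spectrum analytics for retinal-bound pigments.

The absorption maximum (lambda_max) of a microbial rhodopsin reports the
protonation state of the Schiff base and its counterion environment, so
peak positions and shifts between variants are primary observables. This
module extracts lambda_max (with optional sub-grid parabolic refinement),
computes spectral shifts, fits pH titrations with a Henderson-Hasselbalch
sigmoid to obtain pKa values, and fits generic 4-parameter logistic
midpoints for thermostability (Tm) or binding (midpoint on log
concentration) series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

__all__ = [
    "Spectrum", "TitrationSeries", "SigmoidFit", "TitrationFit",
    "FlatSpectrumError", "EdgePeakError",
    "find_lambda_max", "spectral_shift", "fit_titration_pka",
    "fit_sigmoid_midpoint", "SPECTRUM_PRESETS", "gaussian_band_spectrum",
]


class FlatSpectrumError(ValueError):
    """Spectrum has no usable peak (constant within the window)."""


class EdgePeakError(ValueError):
    """Argmax sits on the window edge; the true peak may lie outside."""


@dataclass
class Spectrum:
    """Absorbance (AU) on a strictly increasing wavelength grid (nm)."""

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths_nm.shape != self.absorbance.shape:
            raise ValueError("axes differ in length")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")


@dataclass
class TitrationSeries:
    """Spectra acquired over a pH series, sharing one wavelength grid."""

    ph_values: np.ndarray
    spectra: list[Spectrum]
    readout_nm: float

    def __post_init__(self):
        self.ph_values = np.asarray(self.ph_values, dtype=float)
        if self.ph_values.size < 4:
            raise ValueError("need >= 4 pH points for a titration fit")
        if len(self.spectra) != self.ph_values.size:
            raise ValueError("one spectrum required per pH value")
        wl = self.spectra[0].wavelengths_nm
        for sp in self.spectra[1:]:
            if not np.array_equal(sp.wavelengths_nm, wl):
                raise ValueError("titration spectra must share one grid")

    def readout(self) -> np.ndarray:
        """Absorbance at the readout wavelength per pH (linear interpolation)."""
        return np.array([
            float(np.interp(self.readout_nm, sp.wavelengths_nm, sp.absorbance))
            for sp in self.spectra
        ])


@dataclass
class SigmoidFit:
    lower: float
    upper: float
    midpoint: float
    hill: float
    residual_norm: float
    midpoint_stderr: float | None = None
    extrapolated: bool = False
    log_x: bool = False


@dataclass
class TitrationFit:
    pka: float
    hill: float
    a_acid: float
    a_base: float
    residual_norm: float
    pka_stderr: float | None = None
    extrapolated: bool = False
    poor_fit: bool = False


# ---------------------------------------------------------------------------
# peak analytics
# ---------------------------------------------------------------------------

def find_lambda_max(spec: Spectrum, window_nm: tuple[float, float] | None = None,
                    refine: bool = False) -> float:
    """Wavelength of maximum absorbance.

    ``refine`` applies 3-point parabolic interpolation around the grid
    argmax; ties break toward the shortest wavelength with a warning. A
    flat spectrum or an argmax at the window edge raises.
    """
    wl, a = spec.wavelengths_nm, spec.absorbance
    if window_nm is not None:
        lo, hi = window_nm
        m = (wl >= lo) & (wl <= hi)
        if m.sum() < 3:
            raise ValueError("window contains fewer than 3 grid points")
        wl, a = wl[m], a[m]
    if np.ptp(a) == 0:
        raise FlatSpectrumError(f"spectrum {spec.label!r} is flat; no peak")
    amax = a.max()
    ties = np.flatnonzero(a == amax)
    if ties.size > 1:
        warnings.warn(
            f"{ties.size} grid points tie for the maximum; "
            "reporting the shortest wavelength"
        )
    i = int(ties[0])
    if i == 0 or i == a.size - 1:
        raise EdgePeakError(
            f"absorbance maximum sits at the window edge ({wl[i]:g} nm); "
            "the true peak may lie outside"
        )
    if not refine:
        return float(wl[i])
    y0, y1, y2 = a[i - 1], a[i], a[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(wl[i])
    delta = 0.5 * (y0 - y2) / denom
    # parabolic vertex on a locally uniform grid around the argmax
    h = 0.5 * (wl[i + 1] - wl[i - 1])
    return float(wl[i] + delta * h)


def spectral_shift(a: Spectrum, b: Spectrum, *, refine: bool = False,
                   window_nm: tuple[float, float] | None = None) -> float:
    """Signed shift lambda_max(a) - lambda_max(b) in nm.

    Reported on the raw grid argmax by default so integer-grid fixtures
    yield exact integers; refinement is opt-in.
    """
    return (find_lambda_max(a, window_nm, refine)
            - find_lambda_max(b, window_nm, refine))


# ---------------------------------------------------------------------------
# sigmoid fits
# ---------------------------------------------------------------------------

def _titration_model(ph, a_acid, a_base, pka, hill):
    return a_acid + (a_base - a_acid) / (1.0 + 10.0 ** (hill * (pka - ph)))


def fit_titration_pka(series: TitrationSeries, *,
                      poor_fit_fraction: float = 0.05) -> TitrationFit:
    """Henderson-Hasselbalch fit of absorbance-vs-pH at the readout wavelength.

    Model: A(pH) = A_acid + (A_base - A_acid) / (1 + 10^(n*(pKa - pH))).
    Confidence information comes from the Jacobian-based standard errors.
    A midpoint outside the sampled pH range is flagged ``extrapolated``;
    a residual RMS above ``poor_fit_fraction`` of the response span flags
    ``poor_fit`` (e.g. a double transition forced through one sigmoid).
    """
    ph = series.ph_values
    y = series.readout()
    if np.ptp(y) == 0:
        raise ValueError("readout absorbance does not span a transition")
    model = lmfit.Model(_titration_model)
    params = model.make_params(
        a_acid=float(y[np.argmin(ph)]), a_base=float(y[np.argmax(ph)]),
        pka=float(ph[np.argmin(np.abs(y - y.mean()))]), hill=1.0)
    params["hill"].set(min=0.05, max=10)
    out = model.fit(y, params, ph=ph)
    pka = float(out.params["pka"].value)
    resid_norm = float(np.linalg.norm(out.residual))
    rms = resid_norm / math.sqrt(y.size)
    return TitrationFit(
        pka=pka,
        hill=float(out.params["hill"].value),
        a_acid=float(out.params["a_acid"].value),
        a_base=float(out.params["a_base"].value),
        residual_norm=resid_norm,
        pka_stderr=(float(out.params["pka"].stderr)
                    if out.params["pka"].stderr is not None else None),
        extrapolated=not (ph.min() <= pka <= ph.max()),
        poor_fit=rms > poor_fit_fraction * np.ptp(y),
    )


def _logistic4(x, lower, upper, midpoint, slope):
    return lower + (upper - lower) / (1.0 + np.exp((midpoint - x) / slope))


def fit_sigmoid_midpoint(x: np.ndarray, response: np.ndarray, *,
                         normalize_to: float | None = None,
                         log_x: bool = False) -> SigmoidFit:
    """4-parameter logistic fit for melting (Tm) or binding midpoints.

    With ``normalize_to`` the responses are first divided by the response
    at that reference x (e.g. the 4 degC incubation in a thermostability
    series), so the reference maps to 1.0. ``log_x`` fits on log10(x) for
    concentration series, reporting the midpoint back on the linear scale.
    Non-sigmoidal (flat) data raise with diagnostics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 points for a 4-parameter logistic fit")
    if normalize_to is not None:
        i = int(np.argmin(np.abs(x - normalize_to)))
        ref = y[i]
        if ref == 0:
            raise ValueError("reference response is zero; cannot normalize")
        y = y / ref
    xf = np.log10(x) if log_x else x
    if np.ptp(y) == 0:
        raise ValueError("response is flat; no sigmoid transition to fit")
    model = lmfit.Model(_logistic4)
    slope0 = (np.ptp(xf) / 10.0) * (1 if y[-1] > y[0] else -1)
    params = model.make_params(lower=float(y.min()), upper=float(y.max()),
                               midpoint=float(np.median(xf)), slope=slope0)
    out = model.fit(y, params, x=xf)
    if not out.success:
        raise RuntimeError(f"4PL fit did not converge: {out.message}")
    lower = float(out.params["lower"].value)
    upper = float(out.params["upper"].value)
    mid = float(out.params["midpoint"].value)
    slope = float(out.params["slope"].value)
    # orientation normalization: upper >= lower, hill sign folded into it
    if upper < lower:
        lower, upper = upper, lower
    hill = 1.0 / slope
    stderr = out.params["midpoint"].stderr
    extrap = not (xf.min() <= mid <= xf.max())
    midpoint = float(10 ** mid) if log_x else mid
    return SigmoidFit(lower=lower, upper=upper, midpoint=midpoint, hill=hill,
                      residual_norm=float(np.linalg.norm(out.residual)),
                      midpoint_stderr=(float(stderr) if stderr is not None else None),
                      extrapolated=extrap, log_x=log_x)


# ---------------------------------------------------------------------------
# fixture presets
# ---------------------------------------------------------------------------

#: Single Gaussian bands (FWHM 100 nm, unit peak) on a 250-750 nm, 1 nm
#: grid. Peak positions are the measured dark-state lambda_max values of
#: the named pigments; the band shape itself is a synthetic stand-in.
SPECTRUM_PRESETS: dict[str, float] = {
    "hckcr1_wt_dark": 521.0,
    "hckcr2_wt_dark": 486.0,
    "hckcr1_d105n": 508.0,
    "hckcr1_d229n": 386.0,
}

PRESET_FWHM_NM = 100.0
PRESET_GRID_NM = (250.0, 750.0, 1.0)


def gaussian_band_spectrum(lmax_nm: float, *, fwhm_nm: float = PRESET_FWHM_NM,
                           grid_nm: tuple[float, float, float] = PRESET_GRID_NM,
                           peak_au: float = 1.0, label: str = "") -> Spectrum:
    lo, hi, step = grid_nm
    wl = np.arange(lo, hi + step / 2, step)
    a = peak_au * np.exp(-4.0 * math.log(2.0) * ((wl - lmax_nm) / fwhm_nm) ** 2)
    return Spectrum(wl, a, label=label)
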