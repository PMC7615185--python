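"""Retinal isomer composition from HPLC oxime peak areas.

Retinal extracted as its oxime resolves into eight species on normal-phase
HPLC: the 15-syn and 15-anti oximes of all-trans, 13-cis, 11-cis and 9-cis
retinal. Peak areas at 360 nm are converted to mole fractions by weighting
each area with the reciprocal molar extinction coefficient at 360 nm:

    fraction_i = (A_i / eps_i) / sum_j (A_j / eps_j)

The default extinction table carries the published per-isomer eps_360
values. A convenience reducer sums the 15-syn/anti pair per C-isomer,
since photoproduct compositions are usually discussed per C=C isomer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IsomerTable", "Composition", "DEFAULT_EPSILON_360",
    "unmix_composition", "composition_difference", "integrate_peaks",
    "reduce_to_c_isomers",
]

#: Molar extinction coefficients at 360 nm (1/(M*cm)) of the retinal
#: oxime species.
DEFAULT_EPSILON_360: dict[str, float] = {
    "all-trans-15-syn": 54_900.0,
    "all-trans-15-anti": 51_600.0,
    "13-cis-15-syn": 49_000.0,
    "13-cis-15-anti": 52_100.0,
    "11-cis-15-syn": 35_000.0,
    "11-cis-15-anti": 29_600.0,
    "9-cis-15-syn": 39_300.0,
    "9-cis-15-anti": 30_600.0,
}

CANONICAL_ISOMERS = tuple(DEFAULT_EPSILON_360)


@dataclass(frozen=True)
class IsomerTable:
    """Isomer name -> eps_360 (1/(M*cm)); defaults to the published values."""

    epsilon_360: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EPSILON_360))

    def __post_init__(self):
        for name, eps in self.epsilon_360.items():
            if eps <= 0:
                raise ValueError(f"eps_360 for {name!r} must be > 0, got {eps}")


@dataclass(frozen=True)
class Composition:
    """Mole fraction per isomer; fractions sum to 1."""

    fractions: dict[str, float]

    def __post_init__(self):
        vals = np.array(list(self.fractions.values()))
        if np.any(vals < -1e-12):
            raise ValueError("mole fractions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"mole fractions sum to {vals.sum():.12g}, not 1")

    def __getitem__(self, name: str) -> float:
        return self.fractions[name]


def unmix_composition(areas: dict[str, float],
                      table: IsomerTable | None = None) -> Composition:
    """Peak areas at 360 nm -> mole fractions via 1/eps weighting."""
    table = table or IsomerTable()
    unknown = set(areas) - set(table.epsilon_360)
    if unknown:
        raise ValueError(f"unknown isomer name(s): {sorted(unknown)}")
    if any(a < 0 for a in areas.values()):
        raise ValueError("peak areas must be >= 0")
    weights = {n: a / table.epsilon_360[n] for n, a in areas.items()}
    total = sum(weights.values())
    if total == 0:
        raise ValueError("all peak areas are zero; composition undefined")
    return Composition({n: w / total for n, w in weights.items()})


def composition_difference(light: Composition, dark: Composition) -> dict[str, float]:
    """Elementwise light - dark change in mole fraction (sums to 0)."""
    if set(light.fractions) != set(dark.fractions):
        raise ValueError(
            "isomer sets differ: "
            f"{sorted(set(light.fractions) ^ set(dark.fractions))}"
        )
    return {n: light[n] - dark[n] for n in light.fractions}


def reduce_to_c_isomers(comp: Composition) -> dict[str, float]:
    """Sum the 15-syn/15-anti pair per C=C isomer."""
    out: dict[str, float] = {}
    for name, f in comp.fractions.items():
        base = name.replace("-15-syn", "").replace("-15-anti", "")
        out[base] = out.get(base, 0.0) + f
    return out


def integrate_peaks(time_min: np.ndarray, absorbance: np.ndarray,
                    windows: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Baseline-corrected trapezoidal peak areas (AU*min) per retention window.

    The baseline under each peak is the straight line between the window's
    endpoint absorbances. Windows must be disjoint and inside the record;
    negative corrected areas are clipped to 0 with a warning.
    """
    t = np.asarray(time_min, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    spans = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (n1, (lo1, hi1)), (n2, (lo2, hi2)) in zip(spans[:-1], spans[1:]):
        if hi1 > lo2:
            raise ValueError(f"retention windows {n1!r} and {n2!r} overlap")
    areas: dict[str, float] = {}
    for name, (lo, hi) in windows.items():
        if lo >= hi or lo < t[0] or hi > t[-1]:
            raise ValueError(
                f"window {name!r} [{lo}, {hi}] min is invalid or outside the record")
        m = (t >= lo) & (t <= hi)
        if m.sum() < 2:
            raise ValueError(f"window {name!r} covers fewer than 2 samples")
        tw, aw = t[m], a[m]
        baseline = np.interp(tw, [tw[0], tw[-1]], [aw[0], aw[-1]])
        area = float(np.trapezoid(aw - baseline, tw))
        if area < 0:
            warnings.warn(f"negative corrected area for {name!r} clipped to 0")
            area = 0.0
        areas[name] = area
    return areas
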