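"""Shared multi-exponential fitting machinery.

Model: y(t) = offset + sum_i a_i * exp(-t / tau_i)

The nonlinear time constants are optimized by Nelder-Mead simplex over
log(tau) with multi-start initialization; at every simplex evaluation the
amplitudes and offset are profiled out by linear least squares (variable
projection). This mirrors standard practice in photocurrent and bleach-trend
fitting, where amplitudes are conditionally linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["ExponentialFit", "ExponentialFitError", "fit_multiexponential"]

_REL_SSE_TOL = 1e-10
_N_STARTS = 8


class ExponentialFitError(RuntimeError):
    """Raised when no restart converges; carries the best parameters seen."""

    def __init__(self, message: str, best: "ExponentialFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class ExponentialFit:
    """Result of a multi-exponential least-squares fit.

    ``taus`` are sorted ascending, with ``amplitudes`` aligned to them.
    ``residual_norm`` is the 2-norm of the residual vector.
    """

    taus: np.ndarray
    amplitudes: np.ndarray
    offset: float
    residual_norm: float
    converged: bool = True
    n_iterations: int = 0
    meta: dict = field(default_factory=dict)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset)
        for a, tau in zip(self.amplitudes, self.taus):
            out = out + a * np.exp(-t / tau)
        return out


def _design_matrix(t: np.ndarray, taus: np.ndarray, with_offset: bool) -> np.ndarray:
    cols = [np.exp(-t[:, None] / taus[None, :])]
    if with_offset:
        cols.append(np.ones((t.size, 1)))
    return np.hstack(cols)


def _profiled_sse(log_taus: np.ndarray, t: np.ndarray, y: np.ndarray,
                  with_offset: bool) -> float:
    taus = np.exp(log_taus)
    if np.any(taus <= 0) or np.any(~np.isfinite(taus)):
        return np.inf
    X = _design_matrix(t, taus, with_offset)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _solve_linear(t: np.ndarray, y: np.ndarray, taus: np.ndarray,
                  with_offset: bool) -> tuple[np.ndarray, float, float]:
    X = _design_matrix(t, taus, with_offset)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    offset = float(coef[-1]) if with_offset else 0.0
    amps = coef[: taus.size]
    return amps, offset, float(np.linalg.norm(r))


def fit_multiexponential(
    t: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    with_offset: bool = True,
    n_starts: int = _N_STARTS,
    seed: int = 20230830,
) -> ExponentialFit:
    """Fit ``offset + sum a_i exp(-t/tau_i)`` with ``n_components`` terms.

    Time is re-referenced to ``t[0]`` internally. Initial time constants for
    each restart are log-spaced across the segment duration with seeded
    multiplicative jitter. Raises :class:`ExponentialFitError` if no restart
    converges, carrying the best parameters found so far.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be 1, 2 or 3")
    if t.size < 5 * n_components:
        raise ValueError(
            f"segment of {t.size} samples too short for {n_components} "
            f"exponential components (need >= {5 * n_components})"
        )
    t0 = t - t[0]
    span = t0[-1]
    if span <= 0:
        raise ValueError("segment must span a positive time interval")
    dt = max(np.min(np.diff(t0)), span * 1e-9)

    rng = np.random.default_rng(seed)
    best: ExponentialFit | None = None
    best_sse = np.inf
    any_converged = False
    for i in range(n_starts):
        # log-spaced tau sets spanning dt .. span, rotated per restart
        lo = np.log(dt) + (np.log(span) - np.log(dt)) * (i + 1) / (n_starts + 1)
        base = np.linspace(lo, np.log(span), n_components)
        jitter = rng.normal(scale=0.15, size=n_components) if i else 0.0
        x0 = base + jitter
        res = minimize(
            _profiled_sse, x0, args=(t0, y, with_offset), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": _REL_SSE_TOL * max(float(y @ y), 1e-30),
                     "maxiter": 4000},
        )
        taus = np.sort(np.exp(res.x))
        amps, offset, rnorm = _solve_linear(t0, y, taus, with_offset)
        fit = ExponentialFit(taus=taus, amplitudes=amps, offset=offset,
                             residual_norm=rnorm, converged=bool(res.success),
                             n_iterations=int(res.nit))
        if rnorm**2 < best_sse:
            best_sse = rnorm**2
            best = fit
        any_converged = any_converged or res.success

    assert best is not None
    if not any_converged:
        raise ExponentialFitError(
            "multi-exponential fit failed to converge in all "
            f"{n_starts} restarts (best residual norm {best.residual_norm:.3g})",
            best=best,
        )
    return best
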