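"""Sensitivity analysis: phase extraction, hyperbolic and response-surface fits.

Sweep responses in this model are typically saturating (hyperbolic) in a
single knob, and pairwise interactions between knobs are summarised by the
cross-term coefficient ``c`` of a fitted second-order response surface
``z = a x^2 + b y^2 + c xy + d x + e y + f``: c > 0 flags synergy, c < 0
antagonism, c ~ 0 independence.  Predictors are rescaled to [0, 1] before
surface fitting, so reported ``c`` values live on the normalized scale and
only their sign/zero classification is unit-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .engine import SimulationResult
from .errors import FitError

__all__ = [
    "HyperbolicFit",
    "QuadraticSurfaceFit",
    "PhaseExtract",
    "extract_phase_values",
    "fit_hyperbola",
    "fit_quadratic_surface",
    "normalized_ratio_series",
    "peak_metrics",
]


@dataclass
class HyperbolicFit:
    """y = baseline + vmax * x / (x + k_half), fitted by least squares."""

    vmax: float
    k_half: float
    baseline: float
    residual_norm: float
    converged: bool

    @property
    def plateau(self) -> float:
        """Asymptotic response at saturating predictor (baseline + vmax)."""
        return self.baseline + self.vmax


@dataclass
class QuadraticSurfaceFit:
    """z = a x^2 + b y^2 + c xy + d x + e y + f (+ cubic terms for order 3)."""

    coefficients: dict[str, float]
    order: int
    residual_norm: float

    @property
    def interaction_c(self) -> float:
        return self.coefficients["c"]


@dataclass
class PhaseExtract:
    """Feeding/fasting samples of one quantity, timed on systemic glucose."""

    feeding_time: float
    fasting_time: float
    feeding_value: float
    fasting_value: float


def extract_phase_values(
    result: SimulationResult, quantity: str, window_start: float = 0.0
) -> PhaseExtract:
    """Sample ``quantity`` at the times of maximal (feeding) and minimal
    (fasting) systemic arterial glucose; ties break toward the earliest time.

    The fasting minimum is searched before the gavage starts (the true
    fasting phase); the feeding maximum over the whole window.  For runs
    without a gavage both samples scan the whole window.
    """
    t = result.time
    mask = t >= window_start
    glc = result.series("glc_sys_art")[mask]
    z = result.series(quantity)[mask]
    tt = t[mask]
    gav = result.scenario.gavage
    pre = (tt <= gav.start_time) if gav.dose_g > 0 else np.ones_like(tt, dtype=bool)
    if not pre.any():
        pre = np.ones_like(tt, dtype=bool)
    i_feed = int(np.argmax(glc))
    i_fast = int(np.flatnonzero(pre)[np.argmin(glc[pre])])
    return PhaseExtract(
        feeding_time=float(tt[i_feed]),
        fasting_time=float(tt[i_fast]),
        feeding_value=float(z[i_feed]),
        fasting_value=float(z[i_fast]),
    )


def fit_hyperbola(
    x: np.ndarray,
    y: np.ndarray,
    baseline: bool = False,
) -> HyperbolicFit:
    """Nonlinear least-squares fit of y = b0 + vmax*x/(x + k_half).

    With ``baseline=False`` the offset b0 is fixed at zero.  Exact on
    noiseless hyperbolic data; a failed fit is reported via ``converged``,
    never silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.unique(x).size < 3:
        raise FitError("hyperbolic fit needs >= 3 distinct x values")
    if np.any(x < 0):
        raise FitError("hyperbolic fit requires x >= 0")

    y0 = float(y[np.argmin(x)]) if baseline else 0.0
    vmax0 = float(np.max(y) - y0)
    if vmax0 == 0:
        vmax0 = 1.0
    pos = x[x > 0]
    k0 = float(np.median(pos)) if pos.size else 1.0

    def resid(theta: np.ndarray) -> np.ndarray:
        vmax, log_k, b0 = theta
        k = math.exp(log_k)
        return b0 + vmax * x / (x + k) - y

    theta0 = np.array([vmax0, math.log(k0), y0])
    if baseline:
        sol = least_squares(resid, theta0, method="lm", xtol=1e-15, ftol=1e-15)
    else:
        sol = least_squares(
            lambda th: resid(np.array([th[0], th[1], 0.0])),
            theta0[:2], method="lm", xtol=1e-15, ftol=1e-15,
        )
    ok = bool(sol.success)
    if baseline:
        vmax, log_k, b0 = sol.x
    else:
        (vmax, log_k), b0 = sol.x, 0.0
    return HyperbolicFit(
        vmax=float(vmax),
        k_half=float(math.exp(log_k)),
        baseline=float(b0),
        residual_norm=float(np.linalg.norm(resid(np.array([vmax, log_k, b0])))),
        converged=ok,
    )


_BASIS_2 = ("a", "b", "c", "d", "e", "f")
_BASIS_3 = _BASIS_2 + ("g_x3", "h_y3", "i_x2y", "j_xy2")


def _design(x: np.ndarray, y: np.ndarray, order: int) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [x**2, y**2, x * y, x, y, np.ones_like(x)]
    names = _BASIS_2
    if order == 3:
        cols += [x**3, y**3, x**2 * y, x * y**2]
        names = _BASIS_3
    return np.column_stack(cols), names


def fit_quadratic_surface(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    order: int = 2,
    normalize: bool = True,
) -> QuadraticSurfaceFit:
    """Linear least-squares fit of the second- (or third-) order surface.

    Predictors are affinely rescaled to [0, 1] when ``normalize`` is set (the
    default), so coefficient magnitudes are comparable across sweeps with
    different units; the sign of the interaction coefficient is unaffected by
    any positive rescaling.
    """
    if order not in (2, 3):
        raise FitError("surface order must be 2 or 3")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if normalize:
        def scale(v: np.ndarray) -> np.ndarray:
            span = v.max() - v.min()
            return (v - v.min()) / span if span > 0 else v * 0.0
        x, y = scale(x), scale(y)
    A, names = _design(x, y, order)
    if np.unique(np.column_stack([x, y]), axis=0).shape[0] < len(names):
        raise FitError(f"need >= {len(names)} distinct (x, y) points for order {order}")
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < len(names):
        # identify which basis directions are unresolvable
        _, s, vt = np.linalg.svd(A)
        null = vt[rank:]
        bad = [names[i] for i in np.argsort(-np.abs(null).sum(axis=0))[: len(names) - rank]]
        raise FitError(f"rank-deficient surface design; deficient basis terms: {bad}")
    resid = float(np.linalg.norm(A @ coef - z))
    return QuadraticSurfaceFit(dict(zip(names, coef)), order, resid)


def normalized_ratio_series(
    test: SimulationResult,
    control: SimulationResult,
    numerator: str,
    denominator: str,
) -> np.ndarray:
    """(num/den)_test over (num/den)_control, pointwise on a shared time grid.

    Points where any denominator is <= 0 are masked to NaN.  Identically 1
    when test and control coincide, and invariant to rescaling the units of
    both runs by a common factor.
    """
    if test.time.shape != control.time.shape or not np.allclose(test.time, control.time):
        raise FitError("test and control runs are not on the same output time grid")
    num_t, den_t = test.series(numerator), test.series(denominator)
    num_c, den_c = control.series(numerator), control.series(denominator)
    out = np.full(num_t.shape, np.nan)
    good = (den_t > 0) & (den_c > 0) & (num_c != 0)
    out[good] = (num_t[good] / den_t[good]) / (num_c[good] / den_c[good])
    return out


def peak_metrics(
    time: np.ndarray, series: np.ndarray, after: float = 0.0, plateau_window: float = 10.0
) -> tuple[float, float, float, float]:
    """(peak value, peak time, rise time, decay half-time) of one series.

    The peak is the global maximum after ``after`` (e.g. gavage start); the
    rise time is peak time minus ``after``; the decay half-time is the first
    time at which the post-peak excess over the late plateau (mean of the
    final ``plateau_window`` minutes) has halved.  A series that never decays
    reports NaN for the half-time rather than a fabricated number.
    """
    time = np.asarray(time, dtype=float)
    series = np.asarray(series, dtype=float)
    if time.size == 0:
        raise FitError("empty series")
    mask = time >= after
    t, zz = time[mask], series[mask]
    i_pk = int(np.argmax(zz))
    peak, t_pk = float(zz[i_pk]), float(t[i_pk])
    rise = t_pk - after
    plateau = float(zz[t >= t[-1] - plateau_window].mean())
    half_level = plateau + 0.5 * (peak - plateau)
    post_t, post_z = t[i_pk:], zz[i_pk:]
    below = np.nonzero(post_z <= half_level)[0]
    if below.size == 0 or peak <= plateau:
        return peak, t_pk, rise, math.nan
    j = below[0]
    if j == 0:
        t_half = post_t[0]
    else:  # linear interpolation across the crossing
        f = (post_z[j - 1] - half_level) / (post_z[j - 1] - post_z[j])
        t_half = post_t[j - 1] + f * (post_t[j] - post_t[j - 1])
    return peak, t_pk, rise, float(t_half - t_pk)
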