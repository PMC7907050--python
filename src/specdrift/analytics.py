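"""Closed-form fixation, absorption, extinction and spectrum results.

These formulas describe the time-changed frequency diffusion

    dX = -X(1-X)(tau0 - tau1) dt + sqrt(X(1-X) psi(X)) dB,
    psi(x) = tau0 (1-x) + tau1 x,

whose absorption behaviour coincides with that of the trait frequency of
the symmetric logistic system conditioned on nonextinction.  The scale
function, speed density and Green's-function identities of
one-dimensional diffusion theory give:

* fixation probability  q(x) = tau1 x / (tau0 (1-x) + tau1 x),
* expected inverse-richness-weighted absorption functional
  E_x[int f(P)/R ds] = (2/psi(x)) { x int_x^1 f(y)/y dy
                                    + (1-x) int_0^x f(y)/(1-y) dy },
* rare-trait asymptotics q(x) ~ (tau1/tau0) x and the trait frequency
  spectrum intensity 2 theta / (tau0 y).

The Feller richness diffusion dR = beta R dt + sqrt(tau R) dB goes
extinct from r with probability exp(-2 r beta / tau); the same value is
obtained after rescaling richness into effective size, which is what
dissolves the apparent paradox that an absent trait's turnover would
control the surviving family's drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .params import ParameterError

__all__ = [
    "AbsorptionSummary",
    "fixation_probability",
    "gillespie_fixation",
    "scale_speed",
    "expected_weighted_absorption",
    "feller_extinction_probability",
    "rare_trait_summary",
    "RareTraitSummary",
    "scaled_fixation_rate",
    "spectrum_intensity",
    "spectrum_integral",
    "absorption_summary",
]

_QUAD_TOL = 1e-10


def _check_taus(tau0: float, tau1: float) -> None:
    if tau0 <= 0 or tau1 <= 0:
        raise ParameterError(f"turnover rates must be > 0 (got tau0={tau0}, tau1={tau1})")


def _psi(x, tau0, tau1):
    return tau0 * (1.0 - x) + tau1 * x


def fixation_probability(x, tau0: float, tau1: float):
    """Probability q(x) that trait 0 fixes from initial frequency x.

    q(x) = tau1 x / (tau0 (1-x) + tau1 x); neutral turnover gives
    q(x) = x.
    """
    _check_taus(tau0, tau1)
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ParameterError("x must lie in [0, 1]")
    out = tau1 * x / (tau0 * (1.0 - x) + tau1 * x)
    return out if out.ndim else float(out)


def gillespie_fixation(p, sigma1_sq: float, sigma2_sq: float):
    """Fixation probability u(p) = sigma2^2 p / (sigma1^2 (1-p) + sigma2^2 p).

    This is the classical offspring-variance form; substituting the
    turnover rates for the variances (sigma1^2 = tau0, sigma2^2 = tau1)
    gives exactly :func:`fixation_probability`.
    """
    if sigma1_sq <= 0 or sigma2_sq <= 0:
        raise ParameterError("offspring variances must be > 0")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p must lie in [0, 1]")
    out = sigma2_sq * p / (sigma1_sq * (1.0 - p) + sigma2_sq * p)
    return out if out.ndim else float(out)


def scale_speed(x, tau0: float, tau1: float):
    """Scale function S, speed density m and scale density s at x.

    S(x) = tau0 x / psi(x),  m(x) = psi(x) / (tau0^2 x (1-x)),
    s(x) = S'(x) = tau0^2 / psi(x)^2, for the time-changed frequency
    diffusion with drift (tau1 - tau0) x (1-x) and variance
    x (1-x) psi(x).  Requires 0 < x < 1 (m and s blow up at the
    boundaries).
    """
    _check_taus(tau0, tau1)
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise ParameterError("scale/speed functions need 0 < x < 1")
    ps = _psi(x, tau0, tau1)
    S = tau0 * x / ps
    m = ps / (tau0**2 * x * (1.0 - x))
    s = tau0**2 / ps**2
    if np.ndim(x):
        return S, m, s
    return float(S), float(m), float(s)


def _scale_S(y, tau0, tau1):
    return tau0 * y / _psi(y, tau0, tau1)


def expected_weighted_absorption(
    x: float,
    tau0: float,
    tau1: float,
    f: Callable[[float], float],
    green_form: bool = False,
) -> float:
    """Expected inverse-richness-weighted time functional up to absorption.

    E_x[int_0^eta f(P)/R ds] = (2/psi(x)) { x int_x^1 f(y)/y dy
    + (1-x) int_0^x f(y)/(1-y) dy } for bounded f on [0, 1].  With
    ``green_form=True`` the equivalent Green's-function representation
    2 q(x) int_x^1 (S(1)-S(y)) m(y) f(y) dy
    + 2 (1-q(x)) int_0^x S(y) m(y) f(y) dy is evaluated instead; the two
    agree up to quadrature error.
    """
    _check_taus(tau0, tau1)
    if not 0.0 <= x <= 1.0:
        raise ParameterError("x must lie in [0, 1]")
    if x in (0.0, 1.0):
        return 0.0
    if green_form:
        q = fixation_probability(x, tau0, tau1)
        S1 = _scale_S(1.0, tau0, tau1)

        def upper(y):
            _, m, _ = scale_speed(y, tau0, tau1)
            return (S1 - _scale_S(y, tau0, tau1)) * m * f(y)

        def lower(y):
            _, m, _ = scale_speed(y, tau0, tau1)
            return _scale_S(y, tau0, tau1) * m * f(y)

        iu, _ = quad(upper, x, 1.0, epsabs=_QUAD_TOL, limit=200)
        il, _ = quad(lower, 0.0, x, epsabs=_QUAD_TOL, limit=200)
        return 2.0 * q * iu + 2.0 * (1.0 - q) * il
    iu, _ = quad(lambda y: f(y) / y, x, 1.0, epsabs=_QUAD_TOL, limit=200)
    il, _ = quad(lambda y: f(y) / (1.0 - y), 0.0, x, epsabs=_QUAD_TOL, limit=200)
    return (2.0 / _psi(x, tau0, tau1)) * (x * iu + (1.0 - x) * il)


@dataclass(frozen=True)
class AbsorptionSummary:
    """Fixation probability and weighted absorption time from frequency x."""

    x: float
    q: float
    expected_weighted_time: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ParameterError("q must lie in [0, 1]")
        if self.expected_weighted_time < 0.0:
            raise ParameterError("expected weighted time must be >= 0")


def absorption_summary(
    x: float, tau0: float, tau1: float, f: Callable[[float], float] = lambda _y: 1.0
) -> AbsorptionSummary:
    """Bundle q(x) and the weighted absorption functional for one x."""
    return AbsorptionSummary(
        x=x,
        q=float(fixation_probability(x, tau0, tau1)),
        expected_weighted_time=expected_weighted_absorption(x, tau0, tau1, f),
    )


def feller_extinction_probability(r0: float, beta: float, tau: float) -> float:
    """Ultimate extinction probability of the Feller richness diffusion.

    exp(-2 r0 beta / tau) for the supercritical case beta >= 0; a
    subcritical or critical branching diffusion dies out almost surely.
    Invariant under the effective-size rescaling
    (r0, tau) -> (r0/s, tau/s).
    """
    if tau <= 0:
        raise ParameterError(f"tau={tau} must be > 0")
    if r0 < 0:
        raise ParameterError(f"r0={r0} must be >= 0")
    if beta <= 0:
        return 1.0
    return math.exp(-2.0 * r0 * beta / tau)


@dataclass(frozen=True)
class RareTraitSummary:
    """Exact vs asymptotic fate of a rare invading trait at frequency x."""

    x: float
    q_exact: float
    q_asymptote: float
    weighted_time_exact: float
    weighted_time_asymptote: float

    @property
    def q_relative_gap(self) -> float:
        return abs(self.q_exact / self.q_asymptote - 1.0)

    @property
    def weighted_time_relative_gap(self) -> float:
        return abs(self.weighted_time_exact / self.weighted_time_asymptote - 1.0)


def rare_trait_summary(x: float, tau0: float, tau1: float) -> RareTraitSummary:
    """Small-frequency behaviour of fixation and weighted absorption.

    As x -> 0, q(x) ~ (tau1/tau0) x and the f = 1 weighted absorption
    functional behaves as (-2 x ln x + 2 x) / tau0: an invading trait
    with fast turnover is purged efficiently.
    """
    _check_taus(tau0, tau1)
    if not 0.0 < x < 1.0:
        raise ParameterError("x must lie in (0, 1)")
    exact_w = (-2.0 * x * math.log(x) - 2.0 * (1.0 - x) * math.log1p(-x)) / _psi(x, tau0, tau1)
    return RareTraitSummary(
        x=x,
        q_exact=float(fixation_probability(x, tau0, tau1)),
        q_asymptote=(tau1 / tau0) * x,
        weighted_time_exact=exact_w,
        weighted_time_asymptote=(-2.0 * x * math.log(x) + 2.0 * x) / tau0,
    )


def scaled_fixation_rate(n: int, tau0: float, tau1: float) -> tuple[float, float]:
    """n * q(1/n) and its large-n limit tau1/tau0.

    Interpreted as the per-time-unit fixation rate of traits injected at
    frequency 1/n; the limit shows fast-turnover invaders are purged.
    """
    _check_taus(tau0, tau1)
    if n < 1:
        raise ParameterError("n must be >= 1")
    return n * float(fixation_probability(1.0 / n, tau0, tau1)), tau1 / tau0


def spectrum_intensity(y, theta: float, tau0: float):
    """Trait-frequency-spectrum intensity 2 theta / (tau0 y) on (0, 1)."""
    if theta <= 0 or tau0 <= 0:
        raise ParameterError("theta and tau0 must be > 0")
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ParameterError("y must lie in (0, 1)")
    out = 2.0 * theta / (tau0 * y)
    return out if out.ndim else float(out)


def spectrum_integral(f: Callable[[float], float], theta: float, tau0: float) -> float:
    """Integral of f against the spectrum intensity 2 theta/(tau0 y).

    Requires f(0) = 0 so the endpoint singularity is integrable; for
    f(y) = y the integral equals 2 theta / tau0 exactly.
    """
    if theta <= 0 or tau0 <= 0:
        raise ParameterError("theta and tau0 must be > 0")
    if abs(f(0.0)) > 1e-12:
        raise ParameterError("spectrum integrand must vanish at 0 (f(0) = 0)")
    val, _ = quad(lambda y: f(y) * 2.0 * theta / (tau0 * y), 0.0, 1.0,
                  epsabs=_QUAD_TOL, limit=200)
    return val
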