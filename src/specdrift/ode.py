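"""Deterministic limit systems and their equilibria.

Three systems are provided:

* the law-of-large-numbers ODE for the generation-scale frequency and
  richness (p, r),

      p' = (d0 - d1) p (1-p) - delta01 p + delta10 (1-p)
      r' = r (d0 p + d1 (1-p)),

  with the cladogenetic adjustment d_i -> d_i + a_i delta_ij;

* the large-carrying-capacity limit with a common capacity, in the
  relative richness variable rt = R/c,

      p'  = p (1-p) (1 - rt) (beta0 - beta1) - rho01 p + rho10 (1-p)
      rt' = rt (1 - rt) (beta0 p + beta1 (1-p)),

  whose interior equilibrium is (rho10/(rho10+rho01), 1);

* the trait-specific-capacity limit with c/c_i -> alpha_i,

      p'  = p (1-p) (beta0 (1-alpha0 rt) - beta1 (1-alpha1 rt))
            - rho01 p + rho10 (1-p)
      rt' = rt (beta0 p (1-alpha0 rt) + beta1 (1-p) (1-alpha1 rt)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import MacroParams, MicroParams, ParameterError

__all__ = [
    "ODESolution",
    "lln_ode",
    "largec_common_ode",
    "largec_traitc_ode",
    "equilibrium_p_infinity",
]

_RTOL = 1e-8
_ATOL = 1e-10


@dataclass
class ODESolution:
    """A solved deterministic trajectory on a time grid."""

    times: np.ndarray
    p: np.ndarray
    r: np.ndarray
    equilibrium: tuple[float, float] | None = None

    @property
    def k(self) -> np.ndarray:
        """Expected trait-0 count p*r."""
        return self.p * self.r

    @property
    def l(self) -> np.ndarray:
        """Expected trait-1 count (1-p)*r."""
        return (1.0 - self.p) * self.r


def _solve(rhs, y0, T, t_eval):
    if t_eval is None:
        t_eval = np.linspace(0.0, T, 201)
    sol = solve_ivp(
        rhs, (0.0, float(T)), y0, t_eval=np.asarray(t_eval, dtype=float),
        method="DOP853", rtol=_RTOL, atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return sol


def lln_ode(
    micro: MicroParams,
    x0: tuple[float, float],
    T: float,
    t_eval=None,
) -> ODESolution:
    """Law-of-large-numbers trajectory of (p, r) on generation time.

    Uses the effective net diversification rates d~_i = d_i + a_i
    delta_ij, so cladogenetic transitions shift the selection intensity
    exactly as in the mean dynamics of the jump chain.
    """
    p0, r0 = float(x0[0]), float(x0[1])
    if not 0.0 <= p0 <= 1.0:
        raise ParameterError(f"p0={p0} must lie in [0, 1]")
    if r0 <= 0.0:
        raise ParameterError(f"r0={r0} must be > 0")
    d0, d1 = micro.dtilde0, micro.dtilde1
    a01, a10 = micro.delta01, micro.delta10

    def rhs(_t, y):
        p, r = y
        return (
            (d0 - d1) * p * (1.0 - p) - a01 * p + a10 * (1.0 - p),
            r * (d0 * p + d1 * (1.0 - p)),
        )

    sol = _solve(rhs, (p0, r0), T, t_eval)
    return ODESolution(times=sol.t, p=sol.y[0], r=sol.y[1])


def largec_common_ode(
    macro: MacroParams,
    x0: tuple[float, float],
    T: float,
    t_eval=None,
) -> ODESolution:
    """Large-capacity deterministic limit with a common capacity.

    The richness variable is relative to the capacity (rt = R/c).
    Reports the interior equilibrium (rho10/(rho10+rho01), 1) when the
    transition rates allow it.
    """
    p0, rt0 = float(x0[0]), float(x0[1])
    if not 0.0 <= p0 <= 1.0:
        raise ParameterError(f"p0={p0} must lie in [0, 1]")
    if not 0.0 < rt0 <= 1.0:
        raise ParameterError(f"relative richness r0={rt0} must lie in (0, 1]")
    b0, b1 = macro.beta0, macro.beta1
    r01, r10 = macro.rho01, macro.rho10

    def rhs(_t, y):
        p, rt = y
        return (
            p * (1.0 - p) * (1.0 - rt) * (b0 - b1) - r01 * p + r10 * (1.0 - p),
            rt * (1.0 - rt) * (b0 * p + b1 * (1.0 - p)),
        )

    sol = _solve(rhs, (p0, rt0), T, t_eval)
    eq = None
    if r01 + r10 > 0.0:
        eq = (r10 / (r10 + r01), 1.0)
    else:
        try:
            eq = (equilibrium_p_infinity(macro), 1.0)
        except ParameterError:
            eq = None
    return ODESolution(times=sol.t, p=sol.y[0], r=sol.y[1], equilibrium=eq)


def largec_traitc_ode(
    macro: MacroParams,
    alpha0: float,
    alpha1: float,
    x0: tuple[float, float],
    T: float,
    t_eval=None,
) -> ODESolution:
    """Large-capacity limit with trait-specific sensitivities alpha_i.

    ``alpha_i`` is the limit of c/c_i; alpha0 = alpha1 = 1 recovers the
    common-capacity system pointwise.  With beta0 = beta1 the selection
    term reduces to beta (alpha1 - alpha0) p (1-p) rt, i.e. K-selection
    favoring the trait less sensitive to competition.
    """
    if alpha0 <= 0 or alpha1 <= 0:
        raise ParameterError("alpha0 and alpha1 must be > 0")
    p0, rt0 = float(x0[0]), float(x0[1])
    if not 0.0 <= p0 <= 1.0:
        raise ParameterError(f"p0={p0} must lie in [0, 1]")
    if rt0 <= 0.0:
        raise ParameterError(f"relative richness r0={rt0} must be > 0")
    b0, b1 = macro.beta0, macro.beta1
    r01, r10 = macro.rho01, macro.rho10

    def rhs(_t, y):
        p, rt = y
        return (
            p * (1.0 - p) * (b0 * (1.0 - alpha0 * rt) - b1 * (1.0 - alpha1 * rt))
            - r01 * p + r10 * (1.0 - p),
            rt * (b0 * p * (1.0 - alpha0 * rt) + b1 * (1.0 - p) * (1.0 - alpha1 * rt)),
        )

    sol = _solve(rhs, (p0, rt0), T, t_eval)
    return ODESolution(times=sol.t, p=sol.y[0], r=sol.y[1])


def equilibrium_p_infinity(macro: MacroParams) -> float:
    """Stable long-run trait-0 frequency on the growth path.

    Solves p(1-p)(beta0-beta1) - rho01 p + rho10 (1-p) = 0 for the root
    in [0, 1].  With both transition rates positive there is a unique
    interior root.  Without transitions the stable equilibrium is
    fixation of the trait with the larger net diversification rate; the
    fully degenerate case (no selection, no transitions) is rejected.
    """
    db = macro.beta0 - macro.beta1
    r01, r10 = macro.rho01, macro.rho10
    if db == 0.0 and r01 == 0.0 and r10 == 0.0:
        raise ParameterError(
            "degenerate equilibrium: beta0 == beta1 with rho01 == rho10 == 0 "
            "makes every frequency stationary"
        )
    if db == 0.0:
        return r10 / (r01 + r10)
    if r01 == 0.0 and r10 == 0.0:
        return 1.0 if db > 0.0 else 0.0
    # -db p^2 + (db - r01 - r10) p + r10 = 0
    coeffs = (-db, db - r01 - r10, r10)
    roots = np.roots(coeffs)
    roots = roots[np.abs(roots.imag) < 1e-12].real
    inside = roots[(roots >= -1e-12) & (roots <= 1.0 + 1e-12)]
    if inside.size == 0:
        raise ParameterError("no equilibrium found in [0, 1]")

    def slope(p):
        return db * (1.0 - 2.0 * p) - r01 - r10

    stable = [p for p in inside if slope(p) < 0.0]
    p_star = stable[0] if stable else inside[0]
    return float(min(max(p_star, 0.0), 1.0))
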