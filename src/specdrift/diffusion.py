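"""Euler-Maruyama integration of the limiting diffusion systems.

The general limit of the rescaled two-type branching chain is the
coupled frequency/richness diffusion

    dP = P(1-P)(f0(R) - f1(R)) dt - rho01 P dt + rho10 (1-P) dt
         + sqrt(P(1-P) psi(P) / R) dB-
    dR = R (beta0 P + beta1 (1-P)) (capacity factor) dt
         + sqrt(R psi(1-P)) dB+

with psi(p) = tau0(1-p) + tau1 p and trait fitness f_i depending on the
capacity mode.  The two driving Brownian motions are correlated unless
tau0 = tau1; their increments are realized exactly in law per step from
two independent standard normals (z0, z1) via the mixing coefficients

    dB+ = sqrt(tau0 P / (tau0 P + tau1(1-P))) dB0
        + sqrt(tau1 (1-P) / (tau0 P + tau1(1-P))) dB1
    dB- = sqrt(tau0 (1-P) / (tau0(1-P) + tau1 P)) dB0
        - sqrt(tau1 P / (tau0(1-P) + tau1 P)) dB1

which reproduces the quadratic covariation
<<P, R>>_t = (tau0 - tau1) * int P(1-P) ds.

One-dimensional reference variants are also provided: the scaled
Wright-Fisher diffusion, the (logistic) Feller richness diffusion, and
the time-changed frequency process X with
dX = -X(1-X)(tau0 - tau1) dt + sqrt(X(1-X) psi(X)) dB, whose fixation
behaviour coincides with that of the conditioned logistic system.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import (
    CapacityConfig,
    CapacityMode,
    MacroParams,
    ParameterError,
    psi as _psi_fn,
)

__all__ = [
    "ConfigurationError",
    "AcceptanceRateError",
    "DiffusionSpec",
    "DiffusionPath",
    "EnsembleEstimate",
    "VARIANTS",
    "step",
    "simulate",
    "simulate_ensemble",
    "simulate_conditioned",
    "mc_fixation",
    "mc_weighted_absorption",
    "covariation_estimate",
    "covariation_arrays",
    "noise_weights",
]

VARIANTS = (
    "general",
    "sym_beta",
    "sym_tau",
    "neutral",
    "quasi_neutral",
    "logistic_common",
    "logistic_trait",
    "wright_fisher",
    "feller",
    "time_changed_X",
)

_PR_VARIANTS = {"general", "sym_beta", "sym_tau", "neutral", "quasi_neutral",
                "logistic_common", "logistic_trait"}
_P_ONLY = {"wright_fisher", "time_changed_X"}
_R_ONLY = {"feller"}


class ConfigurationError(ValueError):
    """Invalid variant/parameter combination."""


class AcceptanceRateError(RuntimeError):
    """Conditioned sampler acceptance rate fell below its floor."""


@dataclass(frozen=True)
class DiffusionSpec:
    """A diffusion variant with its macro parameters and capacity mode.

    ``gamma`` is the selection coefficient of the reference Wright-Fisher
    variant (defaults to beta0 - beta1); ``kappa`` is the common
    turnover/diversification ratio of the quasi-neutral variant and is
    derived from the macro rates when omitted.
    """

    variant: str
    macro: MacroParams
    cap: CapacityConfig = CapacityConfig.none()
    kappa: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; choose one of {VARIANTS}"
            )
        m = self.macro
        if self.variant == "sym_beta" and m.beta0 != m.beta1:
            raise ConfigurationError("sym_beta requires beta0 == beta1")
        if self.variant == "sym_tau" and m.tau0 != m.tau1:
            raise ConfigurationError("sym_tau requires tau0 == tau1")
        if self.variant == "neutral" and (m.beta0 != m.beta1 or m.tau0 != m.tau1):
            raise ConfigurationError("neutral requires beta0 == beta1 and tau0 == tau1")
        if self.variant == "quasi_neutral":
            if m.beta0 <= 0 or m.beta1 <= 0:
                raise ConfigurationError("quasi_neutral requires beta_i > 0")
            k0, k1 = m.tau0 / m.beta0, m.tau1 / m.beta1
            if not math.isclose(k0, k1, rel_tol=1e-9):
                raise ConfigurationError(
                    f"quasi_neutral requires tau0/beta0 == tau1/beta1 (got {k0} vs {k1})"
                )
            if self.kappa is not None and not math.isclose(self.kappa, k0, rel_tol=1e-9):
                raise ConfigurationError("kappa inconsistent with macro rates")
            object.__setattr__(self, "kappa", k0)
        if self.variant == "logistic_common" and self.cap.mode is not CapacityMode.COMMON:
            raise ConfigurationError("logistic_common requires a common capacity c")
        if self.variant == "logistic_trait" and self.cap.mode is not CapacityMode.TRAIT_SPECIFIC:
            raise ConfigurationError("logistic_trait requires capacities c0, c1")
        if self.variant in ("general", "sym_beta", "sym_tau", "neutral", "quasi_neutral"):
            # these variants are defined without diversity dependence
            if self.cap.mode is not CapacityMode.NONE:
                raise ConfigurationError(
                    f"variant {self.variant!r} does not take a capacity; "
                    "use logistic_common/logistic_trait"
                )
        if self.variant == "wright_fisher" and self.gamma is None:
            object.__setattr__(self, "gamma", m.beta0 - m.beta1)

    @property
    def has_p(self) -> bool:
        return self.variant not in _R_ONLY

    @property
    def has_r(self) -> bool:
        return self.variant in _PR_VARIANTS or self.variant in _R_ONLY

    @property
    def p_absorbing(self) -> bool:
        """Whether the frequency boundaries are absorbing (no trait inflow)."""
        if not self.has_p:
            return False
        if self.variant == "time_changed_X":
            return True
        return self.macro.rho01 == 0.0 and self.macro.rho10 == 0.0


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------

def noise_weights(tau0: float, tau1: float, p):
    """Mixing coefficients (u0, u1, w0, w1) of the driving noises.

    dB+ = u0 dB0 + u1 dB1 and dB- = w0 dB0 - w1 dB1 in terms of the two
    independent Brownian motions attached to the trait-0 and trait-1
    richness components.
    """
    p = np.asarray(p, dtype=float)
    denom_plus = tau0 * p + tau1 * (1.0 - p)
    denom_minus = tau0 * (1.0 - p) + tau1 * p
    u0 = np.sqrt(tau0 * p / denom_plus)
    u1 = np.sqrt(tau1 * (1.0 - p) / denom_plus)
    w0 = np.sqrt(tau0 * (1.0 - p) / denom_minus)
    w1 = np.sqrt(tau1 * p / denom_minus)
    return u0, u1, w0, w1


def _coefficients(spec: DiffusionSpec, p, r):
    """Drift and diffusion coefficients (bp, sp, br, sr) at state (p, r).

    For one-dimensional variants the unused pair is returned as zeros.
    Square-root arguments are floored at 0.
    """
    m = spec.macro
    v = spec.variant
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    zeros = np.zeros(np.broadcast(p, r).shape)

    if v == "wright_fisher":
        bp = spec.gamma * p * (1.0 - p) - m.rho01 * p + m.rho10 * (1.0 - p)
        sp = np.sqrt(np.maximum(p * (1.0 - p), 0.0))
        return bp, sp, zeros, zeros

    if v == "time_changed_X":
        bp = -p * (1.0 - p) * (m.tau0 - m.tau1)
        sp = np.sqrt(np.maximum(p * (1.0 - p) * _psi_fn(np.clip(p, 0, 1), m), 0.0))
        return bp, sp, zeros, zeros

    if v == "feller":
        fac = spec.cap.factor(0, r) if spec.cap.mode is not CapacityMode.NONE else 1.0
        br = m.beta0 * r * fac
        sr = np.sqrt(np.maximum(m.tau0 * r, 0.0))
        return zeros, zeros, br, sr

    # coupled (P, R) family
    rsafe = np.maximum(r, 1e-300)
    f0 = m.beta0 * spec.cap.factor(0, r) - m.tau0 / rsafe
    f1 = m.beta1 * spec.cap.factor(1, r) - m.tau1 / rsafe
    bp = p * (1.0 - p) * (f0 - f1) - m.rho01 * p + m.rho10 * (1.0 - p)
    sp = np.sqrt(np.maximum(p * (1.0 - p) * _psi_fn(np.clip(p, 0, 1), m) / rsafe, 0.0))
    br = r * (m.beta0 * spec.cap.factor(0, r) * p + m.beta1 * spec.cap.factor(1, r) * (1.0 - p))
    # psi(1-p) = tau0*p + tau1*(1-p)
    sr = np.sqrt(np.maximum(r * (m.tau0 * p + m.tau1 * (1.0 - p)), 0.0))
    return bp, sp, br, sr


def step(spec: DiffusionSpec, state, dt: float, z):
    """One Euler-Maruyama step from (p, r) given two standard normals.

    ``state`` is the pair (p, r); for frequency-only variants r is
    ignored and for the Feller variant p is ignored.  ``z = (z0, z1)``
    are independent N(0,1) draws; the correlated increments of B- and B+
    are built from them so that the per-step covariance matches the
    limiting covariation law exactly.  The new p is clipped to [0, 1]
    and the new r floored at 0.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    p, r = state
    z0, z1 = z
    bp, sp, br, sr = _coefficients(spec, p, r)
    sqdt = math.sqrt(dt)
    if spec.has_p and spec.has_r:
        u0, u1, w0, w1 = noise_weights(spec.macro.tau0, spec.macro.tau1, p)
        db_minus = sqdt * (w0 * np.asarray(z0) - w1 * np.asarray(z1))
        db_plus = sqdt * (u0 * np.asarray(z0) + u1 * np.asarray(z1))
    else:
        db_minus = sqdt * np.asarray(z0)
        db_plus = sqdt * np.asarray(z0)
    p_new = np.clip(np.asarray(p) + bp * dt + sp * db_minus, 0.0, 1.0) if spec.has_p else np.asarray(p)
    r_new = np.maximum(np.asarray(r) + br * dt + sr * db_plus, 0.0) if spec.has_r else np.asarray(r)
    if np.ndim(p) == 0 and np.ndim(r) == 0:
        return float(p_new), float(r_new)
    return p_new, r_new


# ---------------------------------------------------------------------------
# paths and estimates
# ---------------------------------------------------------------------------

STATUS_RUNNING = 0
STATUS_TRAIT0_FIXED = 1   # P absorbed at 1
STATUS_TRAIT1_FIXED = 2   # P absorbed at 0
STATUS_EXTINCT = 3        # R hit the extinction threshold
_STATUS_LABEL = {
    STATUS_RUNNING: "none",
    STATUS_TRAIT0_FIXED: "trait0_fixed",
    STATUS_TRAIT1_FIXED: "trait1_fixed",
    STATUS_EXTINCT: "extinct",
}


@dataclass
class DiffusionPath:
    """A single diffusion trajectory on a uniform time grid."""

    times: np.ndarray
    p: np.ndarray
    r: np.ndarray
    absorbed_trait: str = "none"   # none | trait0_fixed | trait1_fixed
    extinct: bool = False
    absorption_time: float = np.nan


@dataclass
class EnsembleEstimate:
    """A Monte-Carlo estimate with replicate count and seed provenance."""

    value: float
    std_error: float
    n_replicates: int
    n_rejected: int = 0
    n_unresolved: int = 0
    seed: object = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ParameterError("estimate requires at least one replicate")
        if self.std_error < 0:
            raise ParameterError("standard error must be >= 0")


@dataclass
class BatchResult:
    """Terminal summary of a batch of paths (no trajectories stored)."""

    status: np.ndarray          # per-path terminal status code
    absorption_time: np.ndarray
    integral: np.ndarray | None  # weighted absorption accumulator
    p_final: np.ndarray
    r_final: np.ndarray
    seed: object = None


# ---------------------------------------------------------------------------
# batch engine
# ---------------------------------------------------------------------------

def _default_r_tol(r0: float) -> float:
    return 1e-4 * max(1.0, r0)


def _run_batch(
    spec: DiffusionSpec,
    p0: float,
    r0: float,
    dt: float,
    rng: np.random.Generator,
    n_paths: int,
    t_max: float,
    p_tol: float = 1e-6,
    r_tol: float | None = None,
    f: Callable | None = None,
) -> BatchResult:
    """Advance n_paths until absorption or t_max; no trajectories stored.

    Active lanes are compressed out of the working arrays as they absorb,
    so the cost is proportional to the total number of live lane-steps.
    ``f`` enables the weighted-absorption accumulator: trapezoidal
    accumulation of f(P)/R dt for coupled variants and of f(X) dt for the
    time-changed frequency process.
    """
    has_p, has_r = spec.has_p, spec.has_r
    absorbing = spec.p_absorbing
    if r_tol is None:
        r_tol = _default_r_tol(r0)
    n_steps_max = int(math.ceil(t_max / dt))

    p = np.full(n_paths, float(p0))
    r = np.full(n_paths, float(r0))
    idx = np.arange(n_paths)

    status = np.zeros(n_paths, dtype=np.int8)
    t_abs = np.full(n_paths, np.nan)
    integral = np.zeros(n_paths) if f is not None else None
    p_final = np.full(n_paths, float(p0))
    r_final = np.full(n_paths, float(r0))

    def _g(pv, rv):
        fv = np.asarray(f(pv), dtype=float)
        if fv.ndim == 0:
            fv = np.full_like(pv, float(fv))
        if spec.variant == "time_changed_X":
            return fv
        return fv / np.maximum(rv, r_tol)

    g_prev = _g(p, r) if f is not None else None
    sqdt = math.sqrt(dt)
    two_noise = has_p and has_r
    tau0, tau1 = spec.macro.tau0, spec.macro.tau1

    for step_i in range(1, n_steps_max + 1):
        m = p.size
        if m == 0:
            break
        z0 = rng.standard_normal(m)
        bp, sp, br, sr = _coefficients(spec, p, r)
        if two_noise:
            z1 = rng.standard_normal(m)
            u0, u1, w0, w1 = noise_weights(tau0, tau1, p)
            db_minus = sqdt * (w0 * z0 - w1 * z1)
            db_plus = sqdt * (u0 * z0 + u1 * z1)
        else:
            db_minus = db_plus = sqdt * z0
        if has_p:
            p = np.clip(p + bp * dt + sp * db_minus, 0.0, 1.0)
        if has_r:
            r = np.maximum(r + br * dt + sr * db_plus, 0.0)

        if f is not None:
            g_new = _g(p, r)
            integral[idx] += 0.5 * (g_prev + g_new) * dt
            g_prev = g_new

        # absorption detection: trait boundaries first, then extinction
        newly = np.zeros(m, dtype=np.int8)
        if has_p and absorbing:
            newly[p >= 1.0 - p_tol] = STATUS_TRAIT0_FIXED
            newly[p <= p_tol] = STATUS_TRAIT1_FIXED
        if has_r:
            hit_r = (r <= r_tol) & (newly == STATUS_RUNNING)
            newly[hit_r] = STATUS_EXTINCT
        done = newly != STATUS_RUNNING
        if np.any(done):
            gi = idx[done]
            status[gi] = newly[done]
            t_abs[gi] = step_i * dt
            p_snap = p[done]
            p_snap = np.where(newly[done] == STATUS_TRAIT0_FIXED, 1.0, p_snap)
            p_snap = np.where(newly[done] == STATUS_TRAIT1_FIXED, 0.0, p_snap)
            p_final[gi] = p_snap
            r_final[gi] = np.where(newly[done] == STATUS_EXTINCT, 0.0, r[done])
            keep = ~done
            p, r, idx = p[keep], r[keep], idx[keep]
            if f is not None:
                g_prev = g_prev[keep]

    if idx.size:
        p_final[idx] = p
        r_final[idx] = r
    return BatchResult(
        status=status,
        absorption_time=t_abs,
        integral=integral,
        p_final=p_final,
        r_final=r_final,
    )


def simulate_ensemble(
    spec: DiffusionSpec,
    p0: float,
    r0: float,
    T: float,
    dt: float,
    seed=None,
    n_paths: int = 1,
    p_tol: float = 1e-6,
    r_tol: float | None = None,
):
    """Simulate n_paths trajectories on the full uniform grid [0, T].

    Returns ``(times, P, R, status)`` where P and R have shape
    (n_paths, n_times).  Absorbed components are frozen at their boundary
    values.  Intended for moderate path counts where whole trajectories
    are needed (covariation and convergence studies); the terminal-only
    engine behind :func:`simulate_conditioned` is used for large
    fixation ensembles.
    """
    _check_sim_args(spec, p0, r0, T, dt)
    if r_tol is None:
        r_tol = _default_r_tol(r0)
    rng = np.random.default_rng(seed)
    n_steps = int(round(T / dt))
    times = np.arange(n_steps + 1) * dt
    has_p, has_r = spec.has_p, spec.has_r
    absorbing = spec.p_absorbing
    tau0, tau1 = spec.macro.tau0, spec.macro.tau1
    sqdt = math.sqrt(dt)
    two_noise = has_p and has_r

    P = np.empty((n_paths, n_steps + 1))
    R = np.empty((n_paths, n_steps + 1))
    p = np.full(n_paths, float(p0))
    r = np.full(n_paths, float(r0))
    status = np.zeros(n_paths, dtype=np.int8)
    P[:, 0], R[:, 0] = p, r

    for i in range(1, n_steps + 1):
        active = status == STATUS_RUNNING
        z0 = rng.standard_normal(n_paths)
        z1 = rng.standard_normal(n_paths) if two_noise else None
        if np.any(active):
            pa, ra = p[active], r[active]
            bp, sp, br, sr = _coefficients(spec, pa, ra)
            if two_noise:
                u0, u1, w0, w1 = noise_weights(tau0, tau1, pa)
                dbm = sqdt * (w0 * z0[active] - w1 * z1[active])
                dbp = sqdt * (u0 * z0[active] + u1 * z1[active])
            else:
                dbm = dbp = sqdt * z0[active]
            if has_p:
                p[active] = np.clip(pa + bp * dt + sp * dbm, 0.0, 1.0)
            if has_r:
                r[active] = np.maximum(ra + br * dt + sr * dbp, 0.0)
            newly = np.zeros(n_paths, dtype=np.int8)
            if has_p and absorbing:
                newly[active & (p >= 1.0 - p_tol)] = STATUS_TRAIT0_FIXED
                newly[active & (p <= p_tol)] = STATUS_TRAIT1_FIXED
            if has_r:
                newly[active & (r <= r_tol) & (newly == 0)] = STATUS_EXTINCT
            p[newly == STATUS_TRAIT0_FIXED] = 1.0
            p[newly == STATUS_TRAIT1_FIXED] = 0.0
            r[newly == STATUS_EXTINCT] = 0.0
            status[newly != 0] = newly[newly != 0]
        P[:, i], R[:, i] = p, r
    return times, P, R, status


def _check_sim_args(spec, p0, r0, T, dt):
    if spec.has_p and not (0.0 <= p0 <= 1.0):
        raise ParameterError(f"p0={p0} must lie in [0, 1]")
    if spec.has_r and r0 <= 0:
        raise ParameterError(f"r0={r0} must be > 0")
    if T <= 0 or dt <= 0 or dt > T:
        raise ParameterError("require 0 < dt <= T")


def simulate(
    spec: DiffusionSpec,
    p0: float,
    r0: float,
    T: float,
    dt: float,
    seed=None,
    p_tol: float = 1e-6,
    r_tol: float | None = None,
) -> DiffusionPath:
    """A single trajectory on the uniform grid [0, T] with step dt."""
    times, P, R, status = simulate_ensemble(
        spec, p0, r0, T, dt, seed=seed, n_paths=1, p_tol=p_tol, r_tol=r_tol
    )
    st = int(status[0])
    absorbed_trait = _STATUS_LABEL[st] if st in (STATUS_TRAIT0_FIXED, STATUS_TRAIT1_FIXED) else "none"
    return DiffusionPath(
        times=times,
        p=P[0],
        r=R[0],
        absorbed_trait=absorbed_trait,
        extinct=st == STATUS_EXTINCT,
    )


# ---------------------------------------------------------------------------
# conditioned sampling and Monte-Carlo functionals
# ---------------------------------------------------------------------------

def _default_t_max(spec: DiffusionSpec) -> float:
    # generous horizon; trait absorption times are O(1/psi) for the
    # frequency-only variants and O(c/psi) near a common capacity
    if spec.cap.mode is CapacityMode.COMMON:
        return max(400.0, 40.0 * spec.cap.c)
    return 400.0


def simulate_conditioned(
    spec: DiffusionSpec,
    p0: float,
    r0: float,
    T: float | None,
    dt: float,
    seed,
    n_paths: int,
    f: Callable | None = None,
    acceptance_floor: float = 1e-3,
    p_tol: float = 1e-6,
    r_tol: float | None = None,
) -> BatchResult:
    """Rejection sampler approximating conditioning on nonextinction.

    Simulates until trait absorption (P hits 0 or 1) or richness
    extinction; paths whose richness hits the extinction threshold first
    are rejected.  This approximates the process conditioned on the event
    of ultimate nonextinction (the exact Doob transform of the logistic
    richness diffusion has no closed form).  The returned
    :class:`BatchResult` keeps every path's terminal status; rejected
    paths are those with status ``extinct``.
    """
    if not spec.has_p:
        raise ConfigurationError("conditioned sampling needs a frequency component")
    if not spec.p_absorbing:
        raise ConfigurationError(
            "conditioned sampling requires absorbing frequency boundaries (rho01 = rho10 = 0)"
        )
    if T is None:
        T = _default_t_max(spec)
    _check_sim_args(spec, p0, r0, T, dt)
    rng = np.random.default_rng(seed)
    res = _run_batch(
        spec, p0, r0, dt, rng, n_paths, t_max=T, p_tol=p_tol, r_tol=r_tol, f=f
    )
    res.seed = seed
    n_accept = int(np.sum((res.status == STATUS_TRAIT0_FIXED) | (res.status == STATUS_TRAIT1_FIXED)))
    if n_accept < acceptance_floor * n_paths:
        raise AcceptanceRateError(
            f"acceptance rate {n_accept / n_paths:.2e} below floor {acceptance_floor:.0e} "
            f"({n_accept}/{n_paths} paths absorbed at a trait boundary by T={T})"
        )
    n_unresolved = int(np.sum(res.status == STATUS_RUNNING))
    if n_unresolved:
        warnings.warn(
            f"{n_unresolved} of {n_paths} paths neither absorbed nor extinct by T={T}; "
            "they are excluded from conditioned estimates",
            RuntimeWarning,
            stacklevel=2,
        )
    return res


def mc_fixation(
    spec: DiffusionSpec,
    p0: float,
    r0: float,
    dt: float,
    seed,
    n_paths: int,
    T: float | None = None,
    **kwargs,
) -> EnsembleEstimate:
    """Monte-Carlo fixation probability of trait 0 among accepted paths.

    The estimate is the fraction of accepted (non-extinct) paths absorbed
    at P = 1, with a binomial standard error.
    """
    res = simulate_conditioned(spec, p0, r0, T, dt, seed, n_paths, **kwargs)
    fixed0 = int(np.sum(res.status == STATUS_TRAIT0_FIXED))
    fixed1 = int(np.sum(res.status == STATUS_TRAIT1_FIXED))
    n_accept = fixed0 + fixed1
    q_hat = fixed0 / n_accept
    se = math.sqrt(max(q_hat * (1.0 - q_hat), 1.0 / n_accept) / n_accept)
    return EnsembleEstimate(
        value=q_hat,
        std_error=se,
        n_replicates=n_accept,
        n_rejected=int(np.sum(res.status == STATUS_EXTINCT)),
        n_unresolved=int(np.sum(res.status == STATUS_RUNNING)),
        seed=seed,
    )


def mc_weighted_absorption(
    spec: DiffusionSpec,
    p0: float,
    r0: float,
    dt: float,
    seed,
    n_paths: int,
    f: Callable,
    T: float | None = None,
    **kwargs,
) -> EnsembleEstimate:
    """Monte-Carlo estimate of E_x[int_0^eta f(P)/R ds] over accepted paths.

    For the time-changed frequency process the accumulated quantity is
    f(X) ds, which by the time-change identity estimates the same
    functional.  Trapezoidal accumulation along each accepted path.
    """
    res = simulate_conditioned(spec, p0, r0, T, dt, seed, n_paths, f=f, **kwargs)
    accepted = (res.status == STATUS_TRAIT0_FIXED) | (res.status == STATUS_TRAIT1_FIXED)
    vals = res.integral[accepted]
    n = vals.size
    se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return EnsembleEstimate(
        value=float(vals.mean()),
        std_error=se,
        n_replicates=n,
        n_rejected=int(np.sum(res.status == STATUS_EXTINCT)),
        n_unresolved=int(np.sum(res.status == STATUS_RUNNING)),
        seed=seed,
    )


def mc_extinction(
    spec: DiffusionSpec,
    r0: float,
    T: float,
    dt: float,
    seed,
    n_paths: int,
    p0: float = 1.0,
    r_tol: float | None = None,
) -> EnsembleEstimate:
    """Empirical probability that richness has hit 0 by time T.

    For a supercritical Feller diffusion with rate beta and turnover tau
    the ultimate extinction probability from r0 is exp(-2 r0 beta / tau);
    by moderate T the 'extinct by T' frequency is already within
    Monte-Carlo error of that limit.
    """
    if not spec.has_r:
        raise ConfigurationError("extinction estimate needs a richness component")
    _check_sim_args(spec, p0, r0, T, dt)
    rng = np.random.default_rng(seed)
    res = _run_batch(spec, p0, r0, dt, rng, n_paths, t_max=T, r_tol=r_tol)
    frac = float(np.mean(res.status == STATUS_EXTINCT))
    se = math.sqrt(max(frac * (1.0 - frac), 1.0 / n_paths) / n_paths)
    return EnsembleEstimate(
        value=frac, std_error=se, n_replicates=n_paths, seed=seed
    )


# ---------------------------------------------------------------------------
# covariation
# ---------------------------------------------------------------------------

def covariation_arrays(times, P, R, macro: MacroParams):
    """Realized and plug-in covariation of (P, R) on a grid.

    ``P`` and ``R`` may be single paths (1-d) or path ensembles
    (n_paths, n_times).  The realized covariation is the cumulated sum of
    products of increments; the plug-in form is
    (tau0 - tau1) * int P(1-P) ds by trapezoidal quadrature on the same
    grid.  Both cumulative sequences (aligned with ``times``) are
    returned.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    times = np.asarray(times, dtype=float)
    dP = np.diff(P, axis=1)
    dR = np.diff(R, axis=1)
    realized = np.concatenate(
        [np.zeros((P.shape[0], 1)), np.cumsum(dP * dR, axis=1)], axis=1
    )
    g = P * (1.0 - P)
    dt_arr = np.diff(times)
    trap = 0.5 * (g[:, :-1] + g[:, 1:]) * dt_arr
    plugin = (macro.tau0 - macro.tau1) * np.concatenate(
        [np.zeros((P.shape[0], 1)), np.cumsum(trap, axis=1)], axis=1
    )
    return realized, plugin


def covariation_estimate(path: DiffusionPath, macro: MacroParams):
    """Realized vs plug-in covariation sequences for a single path."""
    realized, plugin = covariation_arrays(path.times, path.p, path.r, macro)
    return realized[0], plugin[0]
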