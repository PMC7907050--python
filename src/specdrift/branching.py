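"""Exact stochastic simulation of the two-type species branching chain.

The state is the pair of species counts (K, L) for traits 0 and 1.  Six
jump types are possible: trait-0 and trait-1 speciation, trait-0 and
trait-1 extinction, and transitions 0->1 and 1->0.  With cladogenetic
transition probabilities a0, a1 the speciation and transition rows become

    (k+1, l)    lambda0*k + a1*delta10*l
    (k, l+1)    lambda1*l + a0*delta01*k
    (k-1, l)    mu0*k
    (k, l-1)    mu1*l
    (k-1, l+1)  (1-a0)*delta01*k
    (k+1, l-1)  (1-a1)*delta10*l

which reduces to the purely anagenetic table at a0 = a1 = 0.  Rates are
linear in the state, so between jumps they are constant and the standard
exponential-clock algorithm is exact.  Under diversity dependence the
speciation/extinction rates are recomputed from the current scaled
richness before every event, which keeps the algorithm exact since the
rates remain piecewise constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import (
    CapacityConfig,
    CapacityMode,
    MacroParams,
    MicroParams,
    ParameterError,
    ScalingConfig,
)

__all__ = [
    "JumpPath",
    "PRPath",
    "EnsembleMean",
    "simulate_jump_process",
    "to_pr",
    "ensemble_mean",
    "rescale_to_evolutionary",
    "sample_states_at",
]


@dataclass
class JumpPath:
    """A realized trajectory of the jump chain.

    ``times`` are strictly increasing event times starting at 0;
    ``states`` holds one (k, l) pair per time.  ``absorbed`` is set when
    the chain reached (0, 0).  ``n_clamped`` counts events at which the
    diversity-dependent speciation rate had to be floored at zero.
    """

    times: np.ndarray
    states: np.ndarray  # shape (m, 2), ints
    absorbed: bool = False
    n_clamped: int = 0
    t_max: float = np.inf

    @property
    def k(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def l(self) -> np.ndarray:
        return self.states[:, 1]

    def states_at(self, grid: Sequence[float]) -> np.ndarray:
        """Right-continuous step evaluation of the path on a time grid."""
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.times, grid, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("grid times must be >= 0")
        return self.states[idx]


@dataclass
class PRPath:
    """Frequency/richness representation of a jump path.

    ``p`` is the fraction of trait-0 species, ``r`` the (possibly
    rescaled) total richness.  After total extinction ``p`` is frozen at
    its last defined value, which under the jump table is necessarily 0
    or 1 since the two traits cannot vanish simultaneously.
    """

    times: np.ndarray
    p: np.ndarray
    r: np.ndarray
    absorbed: bool = False


@dataclass
class EnsembleMean:
    """Empirical ensemble mean of (K, L) on a time grid with standard errors."""

    grid: np.ndarray
    mean_k: np.ndarray
    se_k: np.ndarray
    mean_l: np.ndarray
    se_l: np.ndarray
    m: int


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _diversity_rates(macro: MacroParams, cap: CapacityConfig, n: int, r_scaled: float):
    """Per-lineage (lambda0, mu0, lambda1, mu1) at scaled richness R.

    Floors a negative implied speciation rate at zero, compensating in
    the extinction rate so the net rate d is preserved.  Returns the
    rates and whether clamping occurred.
    """
    rates = []
    clamped = False
    for i, (beta, tau) in enumerate(((macro.beta0, macro.tau0), (macro.beta1, macro.tau1))):
        d = (beta / n) * cap.factor(i, r_scaled)
        lam = (tau + d) / 2.0
        mu = (tau - d) / 2.0
        if lam < 0.0:
            lam, mu = 0.0, -d
            clamped = True
        elif mu < 0.0:
            lam, mu = d, 0.0
            clamped = True
        rates.extend((lam, mu))
    return rates[0], rates[1], rates[2], rates[3], clamped


def simulate_jump_process(
    micro: MicroParams | None,
    x0: tuple[int, int],
    t_max: float,
    seed=None,
    cap: CapacityConfig = CapacityConfig.none(),
    scaling: ScalingConfig = ScalingConfig(1),
    macro: MacroParams | None = None,
    rng: np.random.Generator | None = None,
    max_events: int = 10_000_000,
) -> JumpPath:
    """Exact continuous-time simulation of the two-type jump chain.

    Parameters
    ----------
    micro
        Generation-scale rates.  Required when ``cap.mode == 'none'``;
        under diversity dependence it only supplies the cladogenetic
        probabilities (may be None) while the rates are rebuilt from
        ``macro`` at the current richness before every event.
    x0
        Initial (k, l), componentwise nonnegative.
    t_max
        Horizon on the generation time scale.
    cap, scaling, macro
        Diversity-dependence configuration; ``macro`` and ``scaling``
        are required when ``cap.mode != 'none'``.
    """
    k, l = int(x0[0]), int(x0[1])
    if k < 0 or l < 0:
        raise ParameterError(f"initial state {x0} must be componentwise >= 0")
    if t_max < 0:
        raise ParameterError("t_max must be >= 0")
    diversity = cap.mode is not CapacityMode.NONE
    if diversity and macro is None:
        raise ParameterError("diversity-dependent simulation requires macro parameters")
    if not diversity and micro is None:
        raise ParameterError("micro parameters required when capacity mode is 'none'")

    if rng is None:
        rng = np.random.default_rng(seed)
    n = scaling.n

    if diversity:
        a0 = micro.a0 if micro is not None else 0.0
        a1 = micro.a1 if micro is not None else 0.0
        delta01 = macro.rho01 / n
        delta10 = macro.rho10 / n
    else:
        a0, a1 = micro.a0, micro.a1
        delta01, delta10 = micro.delta01, micro.delta10
        lam0, mu0, lam1, mu1 = micro.lambda0, micro.mu0, micro.lambda1, micro.mu1

    times = [0.0]
    states = [(k, l)]
    t = 0.0
    n_clamped = 0
    absorbed = k == 0 and l == 0

    for _ in range(max_events):
        if k == 0 and l == 0:
            absorbed = True
            break
        if diversity:
            lam0, mu0, lam1, mu1, clamped = _diversity_rates(macro, cap, n, (k + l) / n)
            n_clamped += clamped
        r_k_up = lam0 * k + a1 * delta10 * l
        r_l_up = lam1 * l + a0 * delta01 * k
        r_k_down = mu0 * k
        r_l_down = mu1 * l
        r_01 = (1.0 - a0) * delta01 * k
        r_10 = (1.0 - a1) * delta10 * l
        total = r_k_up + r_l_up + r_k_down + r_l_down + r_01 + r_10
        if total <= 0.0:
            break  # frozen state, no further events
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        u = rng.uniform(0.0, total)
        if u < r_k_up:
            k += 1
        elif u < r_k_up + r_l_up:
            l += 1
        elif u < r_k_up + r_l_up + r_k_down:
            k -= 1
        elif u < r_k_up + r_l_up + r_k_down + r_l_down:
            l -= 1
        elif u < r_k_up + r_l_up + r_k_down + r_l_down + r_01:
            k -= 1
            l += 1
        else:
            k += 1
            l -= 1
        times.append(t)
        states.append((k, l))
    else:
        raise RuntimeError(f"event budget of {max_events} exhausted before t_max={t_max}")

    return JumpPath(
        times=np.asarray(times),
        states=np.asarray(states, dtype=np.int64),
        absorbed=absorbed or (k == 0 and l == 0),
        n_clamped=n_clamped,
        t_max=t_max,
    )


def to_pr(path: JumpPath) -> PRPath:
    """Transform a (K, L) path to the frequency/richness pair (P, R).

    P = K/(K+L) and R = K+L; at total extinction P carries its last
    defined value forward.
    """
    k = path.k.astype(float)
    l = path.l.astype(float)
    r = k + l
    p = np.empty_like(r)
    alive = r > 0
    p[alive] = k[alive] / r[alive]
    # freeze P at the value just before extinction (0 or 1 by construction)
    for i in np.flatnonzero(~alive):
        p[i] = p[i - 1] if i > 0 else 0.0
    return PRPath(times=path.times.copy(), p=p, r=r, absorbed=path.absorbed)


def rescale_to_evolutionary(path: JumpPath, scaling: ScalingConfig) -> PRPath:
    """Map a generation-scale path to evolutionary time.

    Event times are divided by n and the richness by n; the frequency is
    scale-invariant.
    """
    pr = to_pr(path)
    n = scaling.n
    return PRPath(times=pr.times / n, p=pr.p, r=pr.r / n, absorbed=pr.absorbed)


def ensemble_mean(
    micro: MicroParams | None,
    m: int,
    x0: tuple[int, int],
    grid: Sequence[float],
    seed=None,
    cap: CapacityConfig = CapacityConfig.none(),
    scaling: ScalingConfig = ScalingConfig(1),
    macro: MacroParams | None = None,
) -> EnsembleMean:
    """Empirical mean of (K, L) over m independent replicates on a grid.

    Each replicate uses an independent child stream spawned from the base
    seed so that the ensemble is reproducible.
    """
    if m < 1:
        raise ParameterError("replicate count m must be >= 1")
    grid = np.asarray(grid, dtype=float)
    t_max = float(grid.max())
    ss = _as_seedseq(seed)
    children = ss.spawn(m)
    ks = np.empty((m, grid.size))
    ls = np.empty((m, grid.size))
    for j in range(m):
        path = simulate_jump_process(
            micro, x0, t_max, rng=np.random.default_rng(children[j]),
            cap=cap, scaling=scaling, macro=macro,
        )
        st = path.states_at(grid)
        ks[j] = st[:, 0]
        ls[j] = st[:, 1]
    se = 1.0 / np.sqrt(m)
    return EnsembleMean(
        grid=grid,
        mean_k=ks.mean(axis=0),
        se_k=ks.std(axis=0, ddof=1) * se if m > 1 else np.zeros(grid.size),
        mean_l=ls.mean(axis=0),
        se_l=ls.std(axis=0, ddof=1) * se if m > 1 else np.zeros(grid.size),
        m=m,
    )


def sample_states_at(
    m: int,
    t: float,
    seed=None,
    micro: MicroParams | None = None,
    x0: tuple[int, int] = (1, 0),
    cap: CapacityConfig = CapacityConfig.none(),
    scaling: ScalingConfig = ScalingConfig(1),
    macro: MacroParams | None = None,
) -> np.ndarray:
    """(K, L) at generation time t for m independent replicates.

    Convenience sampler used by the weak-convergence study; returns an
    (m, 2) integer array.
    """
    ss = _as_seedseq(seed)
    out = np.empty((m, 2), dtype=np.int64)
    for j, child in enumerate(ss.spawn(m)):
        path = simulate_jump_process(
            micro, x0, t, rng=np.random.default_rng(child),
            cap=cap, scaling=scaling, macro=macro,
        )
        out[j] = path.states_at([t])[0]
    return out
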