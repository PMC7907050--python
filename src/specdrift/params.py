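"""Parameter containers and scalar model functions.

Two parameterizations of the two-type species model are supported:

* **Micro (generation-scale) rates**: per-lineage speciation rates
  ``lambda0, lambda1``, extinction rates ``mu0, mu1``, anagenetic
  transition rates ``delta01, delta10`` and optional cladogenetic
  transition probabilities ``a0, a1``.  Equivalent reparameterization:
  net diversification ``d_i = lambda_i - mu_i`` and turnover
  ``tau_i = lambda_i + mu_i``.

* **Macro (evolutionary-time) rates**: net diversification ``beta_i``,
  turnover ``tau_i`` and transition rates ``rho01, rho10`` acting on the
  slow time scale of ``n`` generations per evolutionary time unit.  The
  micro rates that realize a macro parameter set at scaling level ``n``
  are ``d_i = beta_i / n`` (possibly reduced by a carrying-capacity
  factor), ``tau_i`` unchanged, and ``delta = rho / n``.

The scalar model functions collected here (``psi``, ``fitness``,
``effective_size``, ``selection_coefficient``) are shared by the
diffusion and ODE modules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from enum import Enum
from typing import NamedTuple, Union

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "InvalidScalingError",
    "MicroParams",
    "MacroParams",
    "CapacityMode",
    "CapacityConfig",
    "ScalingConfig",
    "Eigenvalues",
    "micro_from_macro",
    "mean_matrix",
    "growth_eigenvalues",
    "psi",
    "fitness",
    "effective_size",
    "selection_coefficient",
    "to_config",
    "from_config",
    "load_config",
    "dump_config",
]


class ParameterError(ValueError):
    """A parameter value violates its domain constraint."""


class InvalidScalingError(ParameterError):
    """A macro parameter set implies a negative micro rate at the given n."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class MicroParams:
    """Per-lineage rates of the generation-scale branching chain.

    All rates are nonnegative; ``a0, a1`` are cladogenetic transition
    probabilities in [0, 1] (default 0, i.e. purely anagenetic
    transitions).
    """

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    delta01: float
    delta10: float
    a0: float = 0.0
    a1: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda0", "lambda1", "mu0", "mu1", "delta01", "delta10"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v >= 0.0, f"rate {name}={v!r} must be finite and >= 0")
        for name in ("a0", "a1"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"cladogenetic probability {name}={v!r} must lie in [0, 1]")

    # -- (d, tau) reparameterization ------------------------------------
    @property
    def d0(self) -> float:
        return self.lambda0 - self.mu0

    @property
    def d1(self) -> float:
        return self.lambda1 - self.mu1

    @property
    def tau0(self) -> float:
        return self.lambda0 + self.mu0

    @property
    def tau1(self) -> float:
        return self.lambda1 + self.mu1

    @property
    def dtilde0(self) -> float:
        """Effective net diversification of trait 0, d0 + a0*delta01."""
        return self.d0 + self.a0 * self.delta01

    @property
    def dtilde1(self) -> float:
        """Effective net diversification of trait 1, d1 + a1*delta10."""
        return self.d1 + self.a1 * self.delta10

    @classmethod
    def from_dtau(
        cls,
        d0: float,
        d1: float,
        tau0: float,
        tau1: float,
        delta01: float = 0.0,
        delta10: float = 0.0,
        a0: float = 0.0,
        a1: float = 0.0,
    ) -> "MicroParams":
        """Build micro rates from net diversification and turnover.

        Inverts ``d = lambda - mu``, ``tau = lambda + mu``; requires
        ``|d_i| <= tau_i`` so that both rates are nonnegative.
        """
        for i, (d, tau) in enumerate(((d0, tau0), (d1, tau1))):
            if abs(d) > tau:
                raise InvalidScalingError(
                    f"trait {i}: |d|={abs(d)} exceeds turnover tau={tau}; implied rate negative"
                )
        return cls(
            lambda0=(tau0 + d0) / 2.0,
            lambda1=(tau1 + d1) / 2.0,
            mu0=(tau0 - d0) / 2.0,
            mu1=(tau1 - d1) / 2.0,
            delta01=delta01,
            delta10=delta10,
            a0=a0,
            a1=a1,
        )


@dataclass(frozen=True)
class MacroParams:
    """Evolutionary-time-scale rates of the diffusion limit.

    ``beta_i`` may be any real (net growth or decline); turnover
    ``tau_i`` must be strictly positive; transition rates ``rho``
    nonnegative.
    """

    beta0: float
    beta1: float
    tau0: float
    tau1: float
    rho01: float = 0.0
    rho10: float = 0.0

    def __post_init__(self) -> None:
        _require(self.tau0 > 0.0, f"tau0={self.tau0!r} must be > 0")
        _require(self.tau1 > 0.0, f"tau1={self.tau1!r} must be > 0")
        _require(self.rho01 >= 0.0, f"rho01={self.rho01!r} must be >= 0")
        _require(self.rho10 >= 0.0, f"rho10={self.rho10!r} must be >= 0")
        for name in ("beta0", "beta1"):
            _require(np.isfinite(getattr(self, name)), f"{name} must be finite")


class CapacityMode(str, Enum):
    NONE = "none"
    COMMON = "common"
    TRAIT_SPECIFIC = "trait_specific"


@dataclass(frozen=True)
class CapacityConfig:
    """Diversity-dependence mode: no regulation, a common carrying
    capacity ``c``, or trait-specific capacities ``c0, c1``."""

    mode: CapacityMode = CapacityMode.NONE
    c: float | None = None
    c0: float | None = None
    c1: float | None = None

    def __post_init__(self) -> None:
        mode = CapacityMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if mode is CapacityMode.COMMON:
            _require(self.c is not None and self.c > 0, "common capacity c must be > 0")
        elif mode is CapacityMode.TRAIT_SPECIFIC:
            _require(self.c0 is not None and self.c0 > 0, "capacity c0 must be > 0")
            _require(self.c1 is not None and self.c1 > 0, "capacity c1 must be > 0")

    @classmethod
    def none(cls) -> "CapacityConfig":
        return cls(mode=CapacityMode.NONE)

    @classmethod
    def common(cls, c: float) -> "CapacityConfig":
        return cls(mode=CapacityMode.COMMON, c=c)

    @classmethod
    def trait_specific(cls, c0: float, c1: float) -> "CapacityConfig":
        return cls(mode=CapacityMode.TRAIT_SPECIFIC, c0=c0, c1=c1)

    def capacity(self, trait: int) -> float | None:
        """Carrying capacity acting on the given trait (None if unregulated)."""
        if self.mode is CapacityMode.NONE:
            return None
        if self.mode is CapacityMode.COMMON:
            return self.c
        return self.c0 if trait == 0 else self.c1

    def factor(self, trait: int, r):
        """Logistic reduction factor 1 - r/c_trait (1 when unregulated)."""
        cap = self.capacity(trait)
        if cap is None:
            return np.ones_like(np.asarray(r, dtype=float)) if np.ndim(r) else 1.0
        return 1.0 - np.asarray(r, dtype=float) / cap if np.ndim(r) else 1.0 - r / cap


@dataclass(frozen=True)
class ScalingConfig:
    """Scaling parameter n: generations per evolutionary time unit and
    mass scale of the species family."""

    n: int = 1

    def __post_init__(self) -> None:
        _require(int(self.n) == self.n and self.n >= 1, f"n={self.n!r} must be an integer >= 1")
        object.__setattr__(self, "n", int(self.n))


def micro_from_macro(
    macro: MacroParams,
    scaling: ScalingConfig = ScalingConfig(1),
    cap: CapacityConfig = CapacityConfig.none(),
    current_r: float = 0.0,
) -> MicroParams:
    """Generation-scale rates realizing a macro parameter set at level n.

    Sets ``d_i = (beta_i / n) * (1 - current_r / c_i)`` (factor 1 without
    diversity dependence), ``lambda_i = (tau_i + d_i)/2``,
    ``mu_i = (tau_i - d_i)/2`` and ``delta = rho / n``.  ``current_r`` is
    the scaled richness R and is only consulted when the capacity mode is
    not ``none``.

    Raises
    ------
    InvalidScalingError
        If an implied speciation or extinction rate would be negative,
        naming the offending trait.
    """
    n = scaling.n
    out = {}
    for i, (beta, tau) in enumerate(((macro.beta0, macro.tau0), (macro.beta1, macro.tau1))):
        d = (beta / n) * cap.factor(i, current_r)
        lam = (tau + d) / 2.0
        mu = (tau - d) / 2.0
        if lam < 0.0 or mu < 0.0:
            raise InvalidScalingError(
                f"trait {i}: d={d} with tau={tau} implies a negative rate "
                f"(lambda={lam}, mu={mu}); increase n or tau"
            )
        out[f"lambda{i}"], out[f"mu{i}"] = lam, mu
    return MicroParams(
        delta01=macro.rho01 / n,
        delta10=macro.rho10 / n,
        **out,
    )


def mean_matrix(micro: MicroParams) -> np.ndarray:
    """The 2x2 mean (growth-rate) matrix of the branching chain.

    ``A = [[d0 - delta01, delta10], [delta01, d1 - delta10]]`` with the
    cladogenetic adjustment ``d_i -> d_i + a_i * delta_ij`` applied when
    ``a_i > 0``.
    """
    return np.array(
        [
            [micro.dtilde0 - micro.delta01, micro.delta10],
            [micro.delta01, micro.dtilde1 - micro.delta10],
        ]
    )


class Eigenvalues(NamedTuple):
    gamma_minus: float
    gamma_plus: float
    regime: str  # subcritical | critical | supercritical


def growth_eigenvalues(micro: MicroParams, atol: float = 0.0) -> Eigenvalues:
    """Eigenvalues (ascending) of the mean matrix and the growth regime.

    With nonnegative off-diagonals the spectrum is real; the closed form
    of the characteristic polynomial is used.  The regime is classified
    by the sign of the leading eigenvalue gamma_plus.
    """
    A = mean_matrix(micro)
    tr = A[0, 0] + A[1, 1]
    disc = (A[0, 0] - A[1, 1]) ** 2 + 4.0 * A[0, 1] * A[1, 0]
    root = math.sqrt(max(disc, 0.0))
    gm, gp = (tr - root) / 2.0, (tr + root) / 2.0
    if gp > atol:
        regime = "supercritical"
    elif gp < -atol:
        regime = "subcritical"
    else:
        regime = "critical"
    return Eigenvalues(gm, gp, regime)


# ---------------------------------------------------------------------------
# scalar model functions
# ---------------------------------------------------------------------------

def psi(p, macro: MacroParams):
    """Frequency-weighted turnover: psi(p) = tau0*(1-p) + tau1*p."""
    p = np.asarray(p, dtype=float)
    _require(bool(np.all((p >= 0) & (p <= 1))), "p must lie in [0, 1]")
    out = macro.tau0 * (1.0 - p) + macro.tau1 * p
    return out if out.ndim else float(out)


def fitness(trait: int, r, macro: MacroParams, cap: CapacityConfig = CapacityConfig.none()):
    """Trait fitness f_i(r) = beta_i * (capacity factor) - tau_i / r.

    Without diversity dependence the factor is 1; with a common capacity
    it is 1 - r/c; with trait-specific capacities 1 - r/c_i.
    """
    r = np.asarray(r, dtype=float)
    _require(bool(np.all(r > 0)), "richness r must be > 0")
    beta = macro.beta0 if trait == 0 else macro.beta1
    tau = macro.tau0 if trait == 0 else macro.tau1
    out = beta * cap.factor(trait, r) - tau / r
    return out if out.ndim else float(out)


def effective_size(p, r, macro: MacroParams):
    """Effective number of species N = r / psi(p) modulating species drift."""
    r = np.asarray(r, dtype=float)
    _require(bool(np.all(r > 0)), "richness r must be > 0")
    out = r / psi(p, macro)
    return out if np.ndim(out) else float(out)


def selection_coefficient(r, macro: MacroParams, cap: CapacityConfig = CapacityConfig.none()):
    """Species selection coefficient gamma(r) = f0(r) - f1(r)."""
    out = np.asarray(fitness(0, r, macro, cap)) - np.asarray(fitness(1, r, macro, cap))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# flat configuration serialization
# ---------------------------------------------------------------------------

_CONFIG_KEYS = (
    "lambda0", "lambda1", "mu0", "mu1", "delta01", "delta10", "a0", "a1",
    "beta0", "beta1", "tau0", "tau1", "rho01", "rho10",
    "capacity_mode", "c", "c0", "c1", "n",
)


def to_config(
    micro: MicroParams | None = None,
    macro: MacroParams | None = None,
    cap: CapacityConfig | None = None,
    scaling: ScalingConfig | None = None,
) -> dict:
    """Flatten parameter containers into a single key-value block."""
    out: dict = {}
    if micro is not None:
        out.update(asdict(micro))
    if macro is not None:
        out.update(asdict(macro))
    if cap is not None:
        out["capacity_mode"] = cap.mode.value
        for key in ("c", "c0", "c1"):
            v = getattr(cap, key)
            if v is not None:
                out[key] = v
    if scaling is not None:
        out["n"] = scaling.n
    return out


def from_config(block: dict) -> dict:
    """Parse a flat configuration block into parameter containers.

    Returns a dict with any of the keys ``micro``, ``macro``, ``cap``,
    ``scaling`` that the block defines.  Unknown keys are rejected.
    """
    unknown = set(block) - set(_CONFIG_KEYS)
    if unknown:
        raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
    out: dict = {}
    micro_keys = ("lambda0", "lambda1", "mu0", "mu1", "delta01", "delta10")
    if any(k in block for k in micro_keys):
        missing = [k for k in micro_keys if k not in block]
        if missing:
            raise ParameterError(f"incomplete micro parameter block, missing {missing}")
        out["micro"] = MicroParams(
            **{k: float(block[k]) for k in micro_keys},
            a0=float(block.get("a0", 0.0)),
            a1=float(block.get("a1", 0.0)),
        )
    macro_keys = ("beta0", "beta1", "tau0", "tau1")
    if any(k in block for k in macro_keys):
        missing = [k for k in macro_keys if k not in block]
        if missing:
            raise ParameterError(f"incomplete macro parameter block, missing {missing}")
        out["macro"] = MacroParams(
            **{k: float(block[k]) for k in macro_keys},
            rho01=float(block.get("rho01", 0.0)),
            rho10=float(block.get("rho10", 0.0)),
        )
    if "capacity_mode" in block:
        out["cap"] = CapacityConfig(
            mode=CapacityMode(block["capacity_mode"]),
            c=block.get("c"),
            c0=block.get("c0"),
            c1=block.get("c1"),
        )
    if "n" in block:
        out["scaling"] = ScalingConfig(n=int(block["n"]))
    return out


def load_config(path: Union[str, "os.PathLike"]) -> dict:  # noqa: F821
    """Read a JSON or YAML configuration file into parameter containers."""
    with open(path) as fh:
        text = fh.read()
    try:
        block = json.loads(text)
    except json.JSONDecodeError:
        block = yaml.safe_load(text)
    if not isinstance(block, dict):
        raise ParameterError(f"configuration file {path} must contain a mapping")
    return from_config(block)


def dump_config(path: Union[str, "os.PathLike"], **containers) -> None:  # noqa: F821
    """Write parameter containers to a JSON or YAML file (by extension)."""
    block = to_config(**containers)
    text = (
        json.dumps(block, indent=2, sort_keys=True)
        if str(path).endswith(".json")
        else yaml.safe_dump(block, sort_keys=True)
    )
    with open(path, "w") as fh:
        fh.write(text)
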