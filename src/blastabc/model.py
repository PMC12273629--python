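"""Compartment ODE models of mouse blastocyst lineage allocation (E2.5-E4.5).

The base model tracks five host compartments of the pre-implantation embryo:
blastomeres (B), trophectoderm (T), unspecified inner-cell-mass cells (C),
primitive endoderm (P) and epiblast (E).  All cells proliferate with a common
net per-capita rate ``alpha``.  Blastomeres differentiate at total per-capita
rate ``beta``, splitting into unspecified ICM with bias ``rho`` and into
trophectoderm with bias ``1 - rho``.  Unspecified ICM cells specify to
primitive endoderm at per-capita rate ``eta * (C + E)**m`` (FGF4 secreted by
unspecified ICM and epiblast) and to epiblast at per-capita rate
``zeta * P**l`` (feedback from the primitive endoderm, e.g. via basement
membrane deposition).  Setting ``l = 0`` recovers a constant EPI-specification
rate, i.e. the no-PrE-feedback model.

The chimera model adds donor embryonic stem cells, either Fgf4+/+ (``D_plus``)
or Fgf4-/- (``D_minus``), injected at the 8-cell stage.  Donors proliferate at
their own net rate ``alpha_D``, contribute to FGF4 induction when Fgf4+/+
(``eta * (C + E + D_plus)**m``), and crowd host blastomeres outward by
replacing the ICM bias with ``rho_eff = rho0 / (1 + a * (D_plus + D_minus)**n)``.

Model variants used for chimera fitting:

====== ================================================================
F      FGF4 induction only; donors grow at the host rate, no crowding
GF     FGF4 induction + differential donor growth (``alpha_D`` free)
FC     FGF4 induction + crowding; donors grow at the host rate
GFC    FGF4 induction + differential growth + crowding
====== ================================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "BaseParams",
    "ChimeraParams",
    "EmbryoState",
    "Trajectory",
    "base_rhs",
    "chimera_rhs",
    "rho_effective",
    "solve",
    "asymptotic_te_fraction",
    "DEFAULT_BASE_PARAMS",
    "DEFAULT_CHIMERA_PARAMS",
]

#: Canonical compartment order used by every array-valued interface.
SPECIES = ("B", "T", "C", "P", "E", "D_plus", "D_minus")

VARIANTS = ("F", "GF", "FC", "GFC")

_NEG_TOL = 1e-9  # compartments this far below zero are clipped, not errors


class ModelDomainError(ValueError):
    """Raised for states or parameters outside the model's domain."""


@dataclass(frozen=True)
class BaseParams:
    """Rate constants of the base (host-only) embryogenesis model.

    Parameters
    ----------
    alpha : float
        Net per-capita growth rate (1/h), division minus death.
    beta : float
        Per-capita blastomere differentiation rate (1/h).
    rho : float
        Blastomere bias toward unspecified ICM, in [0, 1].
    zeta : float
        EPI-specification rate coefficient (1/h / cells**l).
    l : int
        PrE-feedback exponent, one of {0, 1, 2}.
    eta : float
        PrE-specification rate coefficient (1/h / cells**m).
    m : int
        FGF4-feedback exponent, one of {0, 1, 2}.
    """

    alpha: float
    beta: float
    rho: float
    zeta: float
    l: int
    eta: float
    m: int

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.zeta, self.eta) < 0:
            raise ModelDomainError("rate constants must be non-negative")
        if not 0.0 <= self.rho <= 1.0:
            raise ModelDomainError(f"rho must lie in [0, 1], got {self.rho}")
        for name in ("l", "m"):
            v = getattr(self, name)
            if v not in (0, 1, 2):
                raise ModelDomainError(f"{name} must be in {{0, 1, 2}}, got {v}")


@dataclass(frozen=True)
class ChimeraParams:
    """Parameters of the chimera model: base rates plus donor behaviour.

    ``base.rho`` is interpreted as ``rho0``, the uncrowded ICM bias.  The
    crowding feedback divides it by ``1 + a * (D+ + D-)**n``.  Variant
    constraints are enforced at construction: F fixes ``alpha_D = alpha`` and
    ``a = 0``; GF fixes ``a = 0``; FC fixes ``alpha_D = alpha``.
    """

    base: BaseParams
    alpha_D: float
    a: float = 0.0
    n: int = 1
    variant: str = "GFC"

    def __post_init__(self) -> None:
        if self.alpha_D < 0 or self.a < 0:
            raise ModelDomainError("alpha_D and a must be non-negative")
        if self.n not in (0, 1, 2):
            raise ModelDomainError(f"n must be in {{0, 1, 2}}, got {self.n}")
        if self.variant not in VARIANTS:
            raise ModelDomainError(f"variant must be one of {VARIANTS}")
        if self.variant in ("F", "FC") and self.alpha_D != self.base.alpha:
            raise ModelDomainError(f"variant {self.variant} requires alpha_D == alpha")
        if self.variant in ("F", "GF") and self.a != 0.0:
            raise ModelDomainError(f"variant {self.variant} requires a == 0")


@dataclass(frozen=True)
class EmbryoState:
    """Cell counts per compartment at one time point."""

    t: float = 0.0
    B: float = 0.0
    T: float = 0.0
    C: float = 0.0
    P: float = 0.0
    E: float = 0.0
    D_plus: float = 0.0
    D_minus: float = 0.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise ModelDomainError(f"compartment {name} must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, t: float, y: Sequence[float]) -> "EmbryoState":
        return cls(t, *(float(v) for v in y))

    @property
    def total(self) -> float:
        return float(sum(getattr(self, name) for name in SPECIES))

    @property
    def host_total(self) -> float:
        return float(self.B + self.T + self.C + self.P + self.E)

    @property
    def donor_total(self) -> float:
        return float(self.D_plus + self.D_minus)


#: 8-cell morula: eight blastomeres, nothing else.
MORULA = EmbryoState(B=8.0)


def injected_morula(donor_genotype: str, n_donor: int) -> EmbryoState:
    """Initial condition for a chimera: 8 blastomeres plus injected ESCs.

    ``donor_genotype`` is ``"plus"`` (Fgf4+/+) or ``"minus"`` (Fgf4-/-).
    """
    if donor_genotype == "plus":
        return EmbryoState(B=8.0, D_plus=float(n_donor))
    if donor_genotype == "minus":
        return EmbryoState(B=8.0, D_minus=float(n_donor))
    raise ModelDomainError(f"unknown donor genotype {donor_genotype!r}")


def rho_effective(rho0: float, a: float, n: int, donors: float) -> float:
    """Crowded ICM bias ``rho0 / (1 + a * donors**n)``.

    ``n = 1`` recovers the plain hyperbolic crowding function; ``n = 0``
    makes the reduction donor-count-independent (but still requires donors
    to be present: with zero donors there is nothing to crowd, so the bias
    is ``rho0`` regardless of ``n`` and the base model is recovered exactly).
    """
    if donors <= 0:
        return rho0
    return rho0 / (1.0 + a * donors**n)


def _rhs_array(y: np.ndarray, params: BaseParams | ChimeraParams) -> np.ndarray:
    """RHS over the full 7-species array; shared by ODE solver and tests."""
    if isinstance(params, ChimeraParams):
        bp = params.base
        alpha_D = params.alpha_D
        rho = rho_effective(bp.rho, params.a, params.n, y[5] + y[6])
        fgf_pool = y[2] + y[4] + y[5]  # C + E + D_plus
    else:
        bp = params
        alpha_D = 0.0
        rho = bp.rho
        fgf_pool = y[2] + y[4]  # C + E

    B, T, C, P, E, Dp, Dm = np.maximum(y, 0.0)  # guard transient undershoot
    pre_rate = bp.eta * max(fgf_pool, 0.0) ** bp.m  # per-capita C -> P
    epi_rate = bp.zeta * P**bp.l                    # per-capita C -> E

    dB = bp.alpha * B - bp.beta * B
    dT = bp.alpha * T + (1.0 - rho) * bp.beta * B
    dC = bp.alpha * C + rho * bp.beta * B - pre_rate * C - epi_rate * C
    dP = bp.alpha * P + pre_rate * C
    dE = bp.alpha * E + epi_rate * C
    return np.array([dB, dT, dC, dP, dE, alpha_D * Dp, alpha_D * Dm])


def base_rhs(state: EmbryoState, params: BaseParams) -> dict[str, float]:
    """Per-compartment rates of change of the base model.

    The state must have no donor cells.  Returns a mapping over the five host
    compartments.
    """
    if state.D_plus != 0 or state.D_minus != 0:
        raise ModelDomainError("base model admits no donor cells")
    dy = _rhs_array(state.to_array(), params)
    return dict(zip(SPECIES[:5], dy[:5].tolist()))


def chimera_rhs(state: EmbryoState, params: ChimeraParams) -> dict[str, float]:
    """Per-compartment rates of change of the chimera model (7 compartments)."""
    if state.D_plus > 0 and state.D_minus > 0:
        raise ModelDomainError(
            "chimera model assumes a single donor genotype per embryo"
        )
    dy = _rhs_array(state.to_array(), params)
    return dict(zip(SPECIES, dy.tolist()))


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered model solution sampled on a grid.

    ``y`` has shape ``(len(t), 7)`` with columns in :data:`SPECIES` order.
    """

    t: np.ndarray
    y: np.ndarray
    params: BaseParams | ChimeraParams = field(repr=False, default=None)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if y.shape != (t.size, len(SPECIES)):
            raise ValueError("y must have shape (len(t), 7)")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    @property
    def t_max(self) -> float:
        return float(self.t[-1])

    @property
    def states(self) -> list[EmbryoState]:
        return [EmbryoState.from_array(ti, yi) for ti, yi in zip(self.t, self.y)]

    def column(self, species: str) -> np.ndarray:
        return self.y[:, SPECIES.index(species)]

    def columns(self, species: Sequence[str]) -> np.ndarray:
        idx = [SPECIES.index(s) for s in species]
        return self.y[:, idx]

    @property
    def final_state(self) -> EmbryoState:
        return EmbryoState.from_array(self.t[-1], self.y[-1])

    def totals(self) -> np.ndarray:
        return self.y.sum(axis=1)

    def state_at(self, t: float) -> EmbryoState:
        """State at the last grid time <= t (step interpolation)."""
        if t < self.t[0] or t > self.t[-1]:
            raise ValueError(f"time {t} outside trajectory range")
        i = int(np.searchsorted(self.t, t, side="right")) - 1
        return EmbryoState.from_array(self.t[i], self.y[i])

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(self.y, columns=list(SPECIES)).assign(t=self.t)[
            ["t", *SPECIES]
        ]


class SolverError(RuntimeError):
    """ODE integration failed; carries the solver's diagnostic message."""


def solve(
    params: BaseParams | ChimeraParams,
    initial: EmbryoState | None = None,
    t_max: float = 48.0,
    t_grid: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the model over [0, t_max], by default with an adaptive
    explicit Runge-Kutta method (RK45).

    Defaults to the 8-cell morula initial condition and an output grid of
    0.1 h.  Prior exploration visits stiff corners of parameter space (large
    feedback coefficients with quadratic exponents); ``method="LSODA"`` is a
    faster choice there.  Compartments slightly below zero (within the
    integration error scale) are clipped to zero on output; larger negativity
    raises :class:`SolverError`.
    """
    if initial is None:
        initial = MORULA
    if t_max < 0:
        raise ModelDomainError("t_max must be non-negative")
    if isinstance(params, ChimeraParams) and initial.D_plus > 0 and initial.D_minus > 0:
        raise ModelDomainError("chimera model assumes a single donor genotype")

    y0 = initial.to_array()
    if t_max == 0:
        return Trajectory(np.array([0.0]), y0[None, :], params)

    if t_grid is None:
        t_grid = np.linspace(0.0, t_max, max(int(round(t_max / 0.1)), 1) + 1)
    t_grid = np.asarray(t_grid, dtype=float)

    sol = solve_ivp(
        lambda _t, y: _rhs_array(y, params),
        (0.0, t_max),
        y0,
        method=method,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(sol.message)
    y = sol.y.T
    # Negativity beyond the integration error scale signals a solver failure;
    # small undershoot consistent with the tolerances is clipped.
    neg_tol = max(_NEG_TOL, 100.0 * (rtol * float(np.abs(y).max()) + atol))
    if y.min() < -neg_tol:
        raise SolverError(f"compartment went negative: min {y.min():.3g}")
    return Trajectory(sol.t, np.clip(y, 0.0, None), params)


def asymptotic_te_fraction(
    params: BaseParams, t_max: float = 48.0, b_tol: float = 1e-3
) -> float:
    """Trophectoderm fraction of all cells once the blastomere pool is spent.

    Solves the base model to ``t_max`` and returns ``T / total`` at the final
    time.  With specification off (``zeta = eta = 0``) this converges to
    ``1 - rho``.  Raises if blastomeres are not exhausted
    (``B / total >= b_tol``) at ``t_max``.
    """
    if params.beta <= 0:
        raise ModelDomainError("beta must be positive for blastomere exhaustion")
    traj = solve(params, t_max=t_max)
    final = traj.final_state
    if final.B / final.total >= b_tol:
        raise SolverError(
            f"blastomeres not exhausted at t={t_max} h "
            f"(B/total={final.B / final.total:.2e}); increase t_max"
        )
    return final.T / final.total


# Reference parameter set used throughout the analysis scripts and the
# synthetic-data generator: net growth 0.06/h (doubling time ~11.5 h), ICM
# bias 0.35, nonlinear feedback l = m = 2, with beta/zeta/eta chosen so the
# 48 h endpoint is a late blastocyst (blastomeres exhausted, unspecified ICM
# mostly resolved into PrE and EPI).  See docs/methods.md.
DEFAULT_BASE_PARAMS = BaseParams(
    alpha=0.06, beta=0.25, rho=0.35, zeta=1.5e-3, l=2, eta=5e-4, m=2
)

DEFAULT_CHIMERA_PARAMS = ChimeraParams(
    base=DEFAULT_BASE_PARAMS, alpha_D=0.02, a=0.05, n=1, variant="GFC"
)


def make_variant(
    base: BaseParams,
    variant: str,
    alpha_D: float | None = None,
    a: float | None = None,
    n: int = 1,
) -> ChimeraParams:
    """Build a chimera parameter set honouring the variant's constraints."""
    if variant in ("F", "FC"):
        alpha_D = base.alpha
    if variant in ("F", "GF"):
        a = 0.0
    if alpha_D is None or a is None:
        raise ModelDomainError(f"variant {variant} needs alpha_D and a")
    return ChimeraParams(base=base, alpha_D=alpha_D, a=a, n=n, variant=variant)
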