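"""Exact stochastic simulation of the lineage-allocation reaction networks.

Each term of the deterministic model becomes one reaction of a continuous-time
Markov chain, simulated with the Gillespie direct method.  State-dependent
propensities (FGF4 induction, PrE feedback, crowding) are recomputed after
every event, so the simulation is exact, not tau-leaped.

The deterministic model uses a *net* growth rate alpha (division minus death).
By default the chain realises this as pure birth at rate alpha per cell, which
matches the net rate with minimal variance; an optional ``death_rate`` splits
it into birth at ``alpha + death_rate`` and death at ``death_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import (
    SPECIES,
    BaseParams,
    ChimeraParams,
    EmbryoState,
    Trajectory,
    rho_effective,
)

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "StochasticEnsemble",
    "build_network",
    "gillespie_run",
    "simulate_ensemble",
    "ensemble_summary",
]

_IDX = {name: i for i, name in enumerate(SPECIES)}


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: a state change and its propensity function."""

    name: str
    change: np.ndarray  # length-7 stoichiometry vector
    propensity: Callable[[np.ndarray], float]


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def propensities(self, y: np.ndarray) -> np.ndarray:
        return np.array([r.propensity(y) for r in self.reactions])


def _unit(src: str, dst: str | None = None) -> np.ndarray:
    v = np.zeros(len(SPECIES))
    if dst is None:  # birth: src -> 2 src
        v[_IDX[src]] = 1
    else:
        v[_IDX[src]] = -1
        v[_IDX[dst]] = 1
    return v


def build_network(
    params: BaseParams | ChimeraParams, death_rate: float = 0.0
) -> ReactionNetwork:
    """Translate a parameter set into its reaction network.

    Base parameters give 5 birth + 4 transition reactions over the host
    compartments; chimera parameters add donor births and the crowding and
    donor-FGF4 modifications of the transition propensities.  A nonzero
    ``death_rate`` d adds a death channel per species and raises each birth
    rate to ``alpha + d`` so the net rate is unchanged.
    """
    if isinstance(params, ChimeraParams):
        bp, alpha_D = params.base, params.alpha_D
        a, n = params.a, params.n
        chimera = True
    else:
        bp, alpha_D = params, 0.0
        a, n = 0.0, 1
        chimera = False

    if death_rate < 0:
        raise ValueError("death_rate must be non-negative")
    host_birth = bp.alpha + death_rate
    donor_birth = alpha_D + death_rate

    def rho_of(y: np.ndarray) -> float:
        return rho_effective(bp.rho, a, n, y[5] + y[6])

    def pre_propensity(y: np.ndarray) -> float:
        pool = y[2] + y[4] + (y[5] if chimera else 0.0)
        return bp.eta * pool**bp.m * y[2]

    reactions: list[Reaction] = []
    host = SPECIES[:5]
    donor = SPECIES[5:]
    for s in host:
        i = _IDX[s]
        reactions.append(
            Reaction(f"birth_{s}", _unit(s), lambda y, i=i: host_birth * y[i])
        )
    if chimera:
        for s in donor:
            i = _IDX[s]
            reactions.append(
                Reaction(f"birth_{s}", _unit(s), lambda y, i=i: donor_birth * y[i])
            )
    reactions.append(
        Reaction("B_to_T", _unit("B", "T"), lambda y: (1.0 - rho_of(y)) * bp.beta * y[0])
    )
    reactions.append(
        Reaction("B_to_C", _unit("B", "C"), lambda y: rho_of(y) * bp.beta * y[0])
    )
    reactions.append(Reaction("C_to_P", _unit("C", "P"), pre_propensity))
    reactions.append(
        Reaction("C_to_E", _unit("C", "E"), lambda y: bp.zeta * y[3] ** bp.l * y[2])
    )
    if death_rate > 0:
        pool = SPECIES if chimera else host
        for s in pool:
            i = _IDX[s]
            v = np.zeros(len(SPECIES))
            v[i] = -1
            reactions.append(
                Reaction(f"death_{s}", v, lambda y, i=i: death_rate * y[i])
            )
    return ReactionNetwork(SPECIES, tuple(reactions))


def gillespie_run(
    network: ReactionNetwork,
    initial: EmbryoState,
    t_max: float,
    seed: int | np.random.Generator = 0,
) -> Trajectory:
    """One exact realisation of the jump process up to ``t_max``.

    Returns a trajectory of post-event states; the final state is held and
    re-emitted at ``t_max``.  Absorbing states terminate early.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = initial.to_array()
    if not np.allclose(y, np.round(y)):
        raise ValueError("Gillespie requires integer initial counts")
    changes = np.stack([r.change for r in network.reactions])

    times = [0.0]
    states = [y.copy()]
    t = 0.0
    while True:
        props = network.propensities(y)
        total = props.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_max:
            break
        j = rng.choice(len(props), p=props / total)
        y = y + changes[j]
        times.append(t)
        states.append(y.copy())
    if times[-1] < t_max:
        times.append(t_max)
        states.append(y.copy())
    return Trajectory(np.array(times), np.stack(states))


@dataclass(frozen=True)
class StochasticEnsemble:
    """Independent Gillespie replicates sharing a base seed."""

    replicates: tuple[Trajectory, ...]
    seed: int
    n_reps: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_reps", len(self.replicates))


def simulate_ensemble(
    network: ReactionNetwork,
    initial: EmbryoState,
    t_max: float,
    n_reps: int,
    seed: int = 0,
) -> StochasticEnsemble:
    """Run ``n_reps`` independent replicates, each on its own child seed."""
    ss = np.random.SeedSequence(seed)
    reps = tuple(
        gillespie_run(network, initial, t_max, np.random.default_rng(child))
        for child in ss.spawn(n_reps)
    )
    return StochasticEnsemble(reps, seed)


def ensemble_summary(
    ensemble: StochasticEnsemble,
    t: float,
    quantiles: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975),
) -> pd.DataFrame:
    """Per-compartment mean, s.d. and quantiles of the ensemble at time ``t``.

    Uses the last-event-before-``t`` state of each replicate.
    """
    if ensemble.n_reps < 2:
        raise ValueError("ensemble summary needs at least two replicates")
    states = np.stack([rep.state_at(t).to_array() for rep in ensemble.replicates])
    out = pd.DataFrame(index=list(SPECIES))
    out["mean"] = states.mean(axis=0)
    out["sd"] = states.std(axis=0, ddof=1)
    for q in quantiles:
        out[f"q{100 * q:g}"] = np.quantile(states, q, axis=0)
    return out
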